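"""Synthetic generator: manifests, scenes, viability signal, texts, boards."""

import numpy as np
import pytest

from seedfusion.synthetic import (DEFAULT_CLASS_COUNTS, DEFAULT_SPECIES,
                                  PlacementError, ViabilitySignalSpec,
                                  default_homography, embryo_ir_means,
                                  generate_manifest, generate_texts,
                                  render_checkerboard, render_scene,
                                  species_by_id)


# ---------------------------------------------------------------- manifests
def test_default_manifest_reproduces_reference_counts():
    m = generate_manifest(DEFAULT_CLASS_COUNTS, seed=0)
    assert len(m) == 6005
    assert m.n_viable == 3077
    assert len(m) - m.n_viable == 2928


def test_empty_manifest_is_allowed():
    m = generate_manifest({"C01": (0, 0, 0)}, seed=0)
    assert len(m) == 0


def test_manifest_determinism_and_uniqueness():
    a = generate_manifest({"C01": (4, 2, 2)}, seed=7)
    b = generate_manifest({"C01": (4, 2, 2)}, seed=7)
    assert [vars(r) for r in a.rows] == [vars(r) for r in b.rows]
    ids = [r.sample_id for r in a.rows]
    assert len(set(ids)) == len(ids)


@pytest.mark.parametrize("counts", [
    {"C01": (-1, 0, 0)},
    {"C01": (4, 5, -1)},
    {"C01": (4, 3, 3)},
])
def test_manifest_rejects_inconsistent_counts(counts):
    with pytest.raises(ValueError):
        generate_manifest(counts, seed=0)


def test_two_tuple_counts_infer_nonviable():
    m = generate_manifest({"C02": (10, 4)}, seed=0)
    assert len(m) == 10 and m.n_viable == 4


# ------------------------------------------------------------------- scenes
def _rows(counts, seed=0, seeds_per_scene=50):
    return generate_manifest(counts, seed=seed,
                             seeds_per_scene=seeds_per_scene).rows


def test_scene_count_conservation_and_bounds():
    rows = _rows({"C01": (1, 1, 0), "C05": (1, 1, 0), "C07": (1, 0, 1)})
    scene = render_scene(rows, seed=3)
    assert len(scene.boxes) == len(scene.labels) == 3
    h, w = scene.rgb_frame.shape[:2]
    for x0, y0, x1, y1 in scene.boxes:
        assert 0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h
    # near-black background outside the boxes
    mask = np.ones((h, w), dtype=bool)
    for x0, y0, x1, y1 in scene.boxes:
        mask[y0:y1, x0:x1] = False
    assert scene.rgb_frame[mask].max() < 0.02


def test_scene_bitwise_determinism():
    rows = _rows({"C03": (4, 2, 2)})
    a = render_scene(rows, seed=11)
    b = render_scene(rows, seed=11)
    assert np.array_equal(a.rgb_frame, b.rgb_frame)
    assert np.array_equal(a.ir_frame, b.ir_frame)
    assert np.array_equal(a.boxes, b.boxes)


def test_rgb_never_reads_viability_when_leak_is_zero():
    viable = _rows({"C04": (3, 3, 0)})
    nonviable = _rows({"C04": (3, 0, 3)})
    a = render_scene(viable, seed=5)
    b = render_scene(nonviable, seed=5)
    assert np.array_equal(a.rgb_frame, b.rgb_frame)
    assert not np.array_equal(a.ir_frame, b.ir_frame)


def test_rgb_leak_darkens_nonviable_surface():
    rows = _rows({"C05": (2, 1, 1)})
    plain = render_scene(rows, seed=5)
    leaky = render_scene(rows, seed=5, rgb_viability_leak=0.3)
    labels = [v for _, v in plain.labels]
    nv = labels.index("non_viable")
    v = labels.index("viable")
    def box_mean(scene, i):
        x0, y0, x1, y1 = scene.boxes[i]
        return scene.rgb_frame[y0:y1, x0:x1].mean()
    assert box_mean(leaky, nv) < box_mean(plain, nv) - 0.02
    assert box_mean(leaky, v) == pytest.approx(box_mean(plain, v), abs=1e-12)


def test_overcrowded_layout_reports_failing_row():
    rows = _rows({"C12": (400, 200, 200)}, seeds_per_scene=400)
    with pytest.raises(PlacementError):
        render_scene(rows, seed=0, scale=0.1)


def test_poisson_layout_places_disjoint_seeds():
    rows = _rows({"C07": (8, 4, 4)})
    scene = render_scene(rows, layout="poisson", seed=2)
    assert len(scene.boxes) == 8  # disjointness asserted inside render


def _many_seed_embryo_means(effect_size, n=200, seed=0):
    spec = ViabilitySignalSpec(effect_size=effect_size, ir_noise_sd=0.01)
    per = n // 2
    rows = _rows({"C05": (n, per, n - per)}, seeds_per_scene=25)
    means, labels = [], []
    by_scene = {}
    for r in rows:
        by_scene.setdefault(r.scene_id, []).append(r)
    for i, sid in enumerate(sorted(by_scene)):
        scene = render_scene(by_scene[sid], viability_spec=spec,
                             seed=seed * 1000 + i)
        means.extend(embryo_ir_means(scene, spec.embryo_fraction))
        labels.extend(v for _, v in scene.labels)
    return np.asarray(means), np.asarray(labels)


def test_zero_effect_size_means_differ_only_by_noise():
    means, labels = _many_seed_embryo_means(0.0)
    viable = means[labels == "viable"]
    nonviable = means[labels == "non_viable"]
    diff = viable.mean() - nonviable.mean()
    se = np.sqrt(viable.var(ddof=1) / len(viable)
                 + nonviable.var(ddof=1) / len(nonviable))
    assert abs(diff) < 3 * se


def test_effect_size_separable_by_threshold_sweep():
    means, labels = _many_seed_embryo_means(0.3)
    y = (labels == "viable").astype(int)
    # brute-force threshold sweep oracle
    best = 0.0
    for t in np.unique(means):
        acc = max(np.mean((means >= t) == y), np.mean((means < t) == y))
        best = max(best, acc)
    assert best >= 0.99


def test_species_recoverable_by_nearest_centroid():
    """Mean colour + box aspect separate the 12 classes at >= 95%."""
    per_class = 50
    counts = {s.class_id: (per_class, per_class, 0) for s in DEFAULT_SPECIES}
    rows = _rows(counts, seeds_per_scene=25)
    by_scene = {}
    for r in rows:
        by_scene.setdefault(r.scene_id, []).append(r)
    feats, labels = [], []
    for i, sid in enumerate(sorted(by_scene)):
        scene = render_scene(by_scene[sid], seed=i)
        for (x0, y0, x1, y1), (cid, _) in zip(scene.boxes, scene.labels):
            patch = scene.rgb_frame[y0:y1, x0:x1]
            seed_px = patch[patch.max(axis=-1) > 0.05]
            aspect = max((x1 - x0) / (y1 - y0), (y1 - y0) / (x1 - x0))
            feats.append(np.r_[seed_px.mean(axis=0), aspect])
            labels.append(cid)
    feats = np.asarray(feats)
    labels = np.asarray(labels)
    feats = (feats - feats.mean(0)) / feats.std(0)
    classes = sorted(set(labels))
    centroids = np.stack([feats[labels == c].mean(0) for c in classes])
    pred = [classes[np.argmin(((f - centroids) ** 2).sum(1))] for f in feats]
    acc = np.mean([p == t for p, t in zip(pred, labels)])
    assert acc >= 0.95


# -------------------------------------------------------------------- texts
def test_texts_distinct_and_contain_shape_fragment():
    texts = generate_texts("C01", 5, seed=1)
    assert len(texts) == 5 and len(set(texts)) == 5
    shape = species_by_id("C01").text_attributes["shape"]
    assert all(shape in t for t in texts)
    assert all(t for t in texts)


def test_texts_upper_bound_and_determinism():
    texts = generate_texts("C09", 10, seed=4)
    assert len(set(texts)) == 10
    assert generate_texts("C09", 10, seed=4) == texts


def test_texts_unknown_class_raises():
    with pytest.raises(KeyError):
        generate_texts("C99", 5, seed=0)


# ------------------------------------------------------------ checkerboards
def test_checkerboard_identity_homography_pairs_match():
    _, _, pairs = render_checkerboard(np.eye(3), (10, 7), 8)
    assert pairs.shape == (54, 2, 2)  # 9 x 6 inner corners
    np.testing.assert_allclose(pairs[:, 0], pairs[:, 1], atol=0)


def test_checkerboard_pure_scale_doubles_coordinates():
    H = np.diag([2.0, 2.0, 1.0])
    _, _, pairs = render_checkerboard(H, (10, 7), 8)
    np.testing.assert_allclose(pairs[:, 1], 2.0 * pairs[:, 0], atol=0)


def test_checkerboard_random_projective_exact_mapping():
    rng = np.random.default_rng(3)
    H = np.eye(3) + rng.normal(0, 0.01, (3, 3))
    H[2, :2] = rng.normal(0, 1e-4, 2)
    H /= H[2, 2]
    assert np.linalg.cond(H) < 100
    _, _, pairs = render_checkerboard(H, (10, 7), 8)
    src = np.column_stack([pairs[:, 0], np.ones(len(pairs))])
    mapped = (H @ src.T)
    mapped = (mapped[:2] / mapped[2]).T
    assert np.abs(mapped - pairs[:, 1]).max() < 1e-9


def test_checkerboard_singular_homography_rejected():
    with pytest.raises(ValueError):
        render_checkerboard(np.zeros((3, 3)), (10, 7), 8)


def test_default_homography_invertible_and_scale_dominated():
    H = default_homography(0.25)
    assert abs(np.linalg.det(H)) > 1e-6
    assert H[0, 0] == pytest.approx(612 / 80, rel=0.05)
    assert H[1, 1] == pytest.approx(512 / 64, rel=0.05)
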