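"""Registration, ROI extraction, normalisation, augmentation, tokenizer."""

import numpy as np
import pytest

from seedfusion._rng import spawn
from seedfusion.preprocessing import (AugmentationConfig, HomographyError,
                                      IMAGENET_MEAN, IMAGENET_STD, Vocabulary,
                                      augment_pair, box_iou, clean_text,
                                      denormalize_sample, estimate_homography,
                                      extract_rois, normalize_sample,
                                      register_ir, tokenize)
from seedfusion.synthetic import (default_homography, generate_corpus,
                                  generate_manifest, render_checkerboard,
                                  render_scene)


# ------------------------------------------------------------- registration
def test_estimate_recovers_true_homography_from_checkerboard():
    H = default_homography(0.25)
    _, _, pairs = render_checkerboard(H, (10, 7), 8)
    hom = estimate_homography(pairs[:, 0], pairs[:, 1])
    np.testing.assert_allclose(hom.matrix, H / H[2, 2], atol=1e-8)
    assert hom.reprojection_error_px < 0.5


def test_estimate_identity_for_identical_points():
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 100, (10, 2))
    hom = estimate_homography(pts, pts)
    np.testing.assert_allclose(hom.matrix, np.eye(3), atol=1e-9)
    assert hom.reprojection_error_px == pytest.approx(0.0, abs=1e-9)


def test_estimate_rejects_underdetermined_and_collinear():
    pts = np.array([[0.0, 0], [1, 1], [2, 2]])
    with pytest.raises(HomographyError):
        estimate_homography(pts, pts)
    line = np.stack([np.arange(8.0), 2 * np.arange(8.0)], axis=1)
    with pytest.raises(HomographyError):
        estimate_homography(line, line)


def test_register_identity_returns_input():
    rng = np.random.default_rng(1)
    ir = rng.uniform(size=(32, 40))
    out = register_ir(ir, np.eye(3), (32, 40))
    np.testing.assert_allclose(out, ir, atol=1e-12)


def test_register_pure_scale_forward_maps_bright_pixel():
    ir = np.zeros((20, 20))
    ir[7, 5] = 1.0
    H = np.diag([2.0, 2.0, 1.0])
    out = register_ir(ir, H, (40, 40))
    r, c = np.unravel_index(out.argmax(), out.shape)
    assert abs(r - 14) <= 1 and abs(c - 10) <= 1


def test_register_zero_frame_stays_zero():
    out = register_ir(np.zeros((16, 16)), default_homography(), (64, 64))
    assert np.all(out == 0)


# ----------------------------------------------------------------------- roi
def _scene(counts, seed=0, **kw):
    rows = generate_manifest(counts, seed=seed, seeds_per_scene=50).rows
    return render_scene(rows, seed=seed, **kw)


def test_extract_rois_covers_ground_truth():
    scene = _scene({"C03": (5, 3, 2)}, seed=4)
    rois = extract_rois(scene.rgb_frame,
                        np.zeros(scene.rgb_frame.shape[:2]),
                        margin_px=3, out_size=32)
    assert len(rois) == 5
    for tb in scene.boxes:
        best = max(box_iou(r[2], tb) for r in rois)
        assert best > 0.5
    # every ROI box contains its truth box
    for rgb_crop, ir_crop, box in rois:
        tb = max(scene.boxes, key=lambda t: box_iou(box, t))
        assert box[0] <= tb[0] and box[1] <= tb[1]
        assert box[2] >= tb[2] and box[3] >= tb[3]
        assert rgb_crop.shape == (32, 32, 3) and ir_crop.shape == (32, 32)


def test_extract_rois_empty_frame():
    assert extract_rois(np.zeros((64, 64, 3)), np.zeros((64, 64))) == []


def test_extract_rois_clips_boxes_at_frame_edge():
    frame = np.zeros((40, 40, 3))
    frame[0:12, 0:12] = 0.8  # seed touching the corner
    rois = extract_rois(frame, np.zeros((40, 40)), margin_px=10, out_size=16)
    assert len(rois) == 1
    x0, y0, x1, y1 = rois[0][2]
    assert (x0, y0) == (0, 0) and x1 <= 40 and y1 <= 40


# ----------------------------------------------------------- normalisation
def test_normalize_centering_and_formula():
    const = np.ones((4, 4, 3)) * IMAGENET_MEAN
    rgb, ir = normalize_sample(const, np.full((4, 4), 0.5))
    np.testing.assert_allclose(rgb, 0.0, atol=1e-12)
    np.testing.assert_allclose(ir, 0.0, atol=1e-12)
    ones = np.ones((2, 2, 3))
    rgb, _ = normalize_sample(ones, np.ones((2, 2)))
    np.testing.assert_allclose(rgb[0, 0], (1 - IMAGENET_MEAN) / IMAGENET_STD)


def test_normalize_roundtrip_and_uint_inputs():
    rng = np.random.default_rng(2)
    rgb8 = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
    ir16 = rng.integers(0, 65536, (8, 8), dtype=np.uint16)
    rgb, ir = normalize_sample(rgb8, ir16)
    back_rgb, back_ir = denormalize_sample(rgb, ir)
    np.testing.assert_allclose(back_rgb, rgb8 / 255.0, atol=1e-6)
    np.testing.assert_allclose(back_ir, ir16 / 65535.0, atol=1e-6)


def test_normalize_rejects_nonfinite():
    bad = np.ones((2, 2, 3))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        normalize_sample(bad, np.ones((2, 2)))


# ------------------------------------------------------------- augmentation
def test_augmentation_keeps_modalities_synchronized():
    cfg = AugmentationConfig(ir_noise_sd=0.0, color_jitter_frac=0.0)
    for seed in range(100):
        rgb = np.zeros((33, 33, 3))
        ir = np.zeros((33, 33))
        rgb[20, 9] = 1.0
        ir[20, 9] = 1.0
        r2, i2, _ = augment_pair(rgb, ir, cfg, spawn(seed, "aug"))
        pos_rgb = np.unravel_index(r2[..., 0].argmax(), r2[..., 0].shape)
        pos_ir = np.unravel_index(i2.argmax(), i2.shape)
        assert pos_rgb == pos_ir


def test_augmentation_identity_config_is_noop():
    cfg = AugmentationConfig(p_flip=0.0, rotation_deg=0.0,
                             scale_range=(1.0, 1.0), color_jitter_frac=0.0,
                             ir_noise_sd=0.0)
    rng = np.random.default_rng(0)
    rgb = rng.uniform(size=(16, 16, 3))
    ir = rng.uniform(size=(16, 16))
    r2, i2, params = augment_pair(rgb, ir, cfg, rng)
    np.testing.assert_array_equal(r2, rgb)
    np.testing.assert_array_equal(i2, ir)
    assert params["enabled"]


def test_augmentation_disabled_returns_inputs():
    cfg = AugmentationConfig(enabled=False)
    rgb = np.ones((4, 4, 3))
    ir = np.ones((4, 4))
    r2, i2, params = augment_pair(rgb, ir, cfg, np.random.default_rng(0))
    assert params == {"enabled": False}
    np.testing.assert_array_equal(r2, rgb)


def test_ir_noise_magnitude_matches_half_normal_mean():
    cfg = AugmentationConfig(p_flip=0.0, rotation_deg=0.0,
                             scale_range=(1.0, 1.0), color_jitter_frac=0.0,
                             ir_noise_sd=0.01)
    ir = np.full((100, 100), 0.5)
    _, i2, _ = augment_pair(np.zeros((100, 100, 3)), ir, cfg,
                            np.random.default_rng(5))
    mad = np.abs(i2 - ir).mean()
    expected = 0.01 * np.sqrt(2 / np.pi)
    assert abs(mad - expected) / expected < 0.10


# ---------------------------------------------------------------- tokenizer
@pytest.fixture(scope="module")
def toy_vocab():
    return Vocabulary.from_corpus(["oval shape seed coat yellow"])


def test_tokenize_construction(toy_vocab):
    out = tokenize("Oval   shape!!", toy_vocab)
    assert clean_text("Oval   shape!!") == "oval shape"
    assert out.token_ids[0] == toy_vocab.cls_id
    assert out.attention_mask.sum() == 4
    ids = out.token_ids[:4]
    assert ids[-1] == toy_vocab.sep_id
    assert np.all(out.token_ids[4:] == toy_vocab.pad_id)


def test_tokenize_truncates_long_input_to_77(toy_vocab):
    text = " ".join(["seed"] * 200)
    out = tokenize(text, toy_vocab)
    assert len(out.token_ids) == 77
    n = int(out.attention_mask.sum())
    assert n == 77
    assert out.token_ids[n - 1] == toy_vocab.sep_id


def test_tokenize_deterministic_and_char_fallback(toy_vocab):
    a = tokenize("unknownword seed", toy_vocab)
    b = tokenize("unknownword seed", toy_vocab)
    np.testing.assert_array_equal(a.token_ids, b.token_ids)
    assert a.attention_mask.sum() > 4  # char pieces expand the unknown word


def test_tokenize_empty_after_cleanup_raises(toy_vocab):
    with pytest.raises(ValueError):
        tokenize("!!! ???", toy_vocab)


def test_tokenizer_total_over_synthetic_corpus():
    corpus = generate_corpus(6, seed=0)
    texts = [t for ts in corpus.values() for t in ts]
    vocab = Vocabulary.from_corpus(texts)
    for t in texts:
        out = tokenize(t, vocab)
        assert out.attention_mask.sum() >= 2
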