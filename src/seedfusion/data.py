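"""End-to-end dataset assembly: manifests -> scenes -> registered crops.

``build_dataset`` exercises the whole acquisition-emulation path: render
each scene, estimate the inter-sensor homography from a synthetic
checkerboard (rather than trusting the generator's true matrix), register
the IR frame into RGB coordinates, extract ROIs, match them to ground
truth boxes, and normalise the crops.  The result is a list of labelled
:class:`~seedfusion.preprocessing.normalize.SeedSample` ready for the
model.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from ._rng import spawn
from .preprocessing import (SeedSample, box_iou, estimate_homography,
                            extract_rois, normalize_sample, register_ir)
from .synthetic import (DatasetManifest, ViabilitySignalSpec,
                        default_homography, generate_manifest,
                        render_checkerboard, render_scene)

__all__ = ["build_dataset", "desk_manifest", "split_by_scene",
           "stratified_split"]


def desk_manifest(per_class: int = 50, viable_fraction: float = 0.5,
                  seed: int = 0, seeds_per_scene: int = 25,
                  class_ids: tuple[str, ...] | None = None) -> DatasetManifest:
    """A reduced manifest for desk-scale experiments (default 600 seeds)."""
    if class_ids is None:
        class_ids = tuple(f"C{i:02d}" for i in range(1, 13))
    viable = int(round(per_class * viable_fraction))
    counts = {cid: (per_class, viable, per_class - viable)
              for cid in class_ids}
    return generate_manifest(counts, seed=seed,
                             seeds_per_scene=seeds_per_scene)


def build_dataset(manifest: DatasetManifest,
                  viability_spec: ViabilitySignalSpec | None = None,
                  scale: float = 0.25, crop_size: int = 64,
                  layout: str = "grid", seed: int = 0,
                  rgb_viability_leak: float = 0.0,
                  iou_match: float = 0.25) -> list[SeedSample]:
    """Render every scene in ``manifest`` and return normalised samples.

    The homography used for registration is *estimated* from checkerboard
    corners rendered under the true sensor geometry, so registration error
    propagates realistically.  ROIs failing to match any ground-truth box
    at ``iou_match`` are dropped (they carry no label).
    """
    if viability_spec is None:
        viability_spec = ViabilitySignalSpec()
    by_scene: dict[str, list] = defaultdict(list)
    for row in manifest.rows:
        by_scene[row.scene_id].append(row)

    true_h = default_homography(scale)
    _, _, corners = render_checkerboard(true_h, grid=(10, 7), square_px=6)
    est = estimate_homography(corners[:, 0], corners[:, 1])

    samples: list[SeedSample] = []
    for scene_id in sorted(by_scene):
        rows = by_scene[scene_id]
        scene = render_scene(rows, viability_spec=viability_spec,
                             layout=layout, scale=scale,
                             seed=spawn(seed, "scene", scene_id).integers(2**31),
                             homography=true_h,
                             rgb_viability_leak=rgb_viability_leak)
        reg = register_ir(scene.ir_frame, est, scene.rgb_frame.shape[:2])
        # the 10 px box margin is defined at full sensor resolution; scale
        # it with the rendered frame so crops stay proportionate
        margin = max(int(round(10 * scale)), 2)
        rois = extract_rois(scene.rgb_frame, reg, margin_px=margin,
                            out_size=crop_size)
        for rgb_crop, ir_crop, box in rois:
            ious = [box_iou(box, tb) for tb in scene.boxes]
            best = int(np.argmax(ious)) if ious else -1
            if best < 0 or ious[best] < iou_match:
                continue
            row = rows[best]
            rgb_n, ir_n = normalize_sample(rgb_crop, ir_crop)
            samples.append(SeedSample(
                rgb=rgb_n, ir=ir_n, class_id=row.class_id,
                viability=row.viability, source_box=box,
                scene_id=scene_id, sample_id=row.sample_id))
    return samples


def split_by_scene(samples: list[SeedSample],
                   fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                   seed: int = 0) -> tuple[list, list, list]:
    """Scene-level train/val/test split (avoids intra-scene leakage)."""
    scenes = sorted({s.scene_id for s in samples})
    rng = spawn(seed, "split")
    order = rng.permutation(len(scenes))
    n_train = max(int(round(fractions[0] * len(scenes))), 1)
    n_val = max(int(round(fractions[1] * len(scenes))), 1)
    train_ids = {scenes[i] for i in order[:n_train]}
    val_ids = {scenes[i] for i in order[n_train:n_train + n_val]}
    train = [s for s in samples if s.scene_id in train_ids]
    val = [s for s in samples if s.scene_id in val_ids]
    test = [s for s in samples
            if s.scene_id not in train_ids and s.scene_id not in val_ids]
    return train, val, test


def stratified_split(samples: list[SeedSample],
                     fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                     seed: int = 0) -> tuple[list, list, list]:
    """Sample-level split stratified by (class, viability)."""
    groups: dict[tuple, list] = defaultdict(list)
    for s in samples:
        groups[(s.class_id, s.viability)].append(s)
    rng = spawn(seed, "stratified-split")
    train, val, test = [], [], []
    for key in sorted(groups):
        members = groups[key]
        order = rng.permutation(len(members))
        n = len(members)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        for pos, idx in enumerate(order):
            if pos < n_train:
                train.append(members[idx])
            elif pos < n_train + n_val:
                val.append(members[idx])
            else:
                test.append(members[idx])
    return train, val, test
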