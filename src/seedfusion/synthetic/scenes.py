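"""Paired RGB / infrared seed-scene rendering.

A scene is a dark conveyor-belt frame holding ellipse-shaped seeds.  The
visible frame carries each species' appearance (colour, aspect, stripes);
the infrared frame images the same geometry through the true inter-sensor
homography at the (much lower) IR resolution.  Seed viability is encoded
*only* in the infrared channel: the embryo region — a concentric central
ellipse covering ``embryo_fraction`` of the seed area — has its mean
intensity depressed by ``effect_size`` for non-viable seeds, a proxy for
the moisture/lipid loss that short-wave infrared responds to.  The RGB
renderer never reads the viability label unless ``rgb_viability_leak`` is
set, so visible-only models cannot recover viability by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .._rng import child_seed, spawn
from .manifest import ManifestRow
from .species import DEFAULT_SPECIES, SpeciesSpec

__all__ = [
    "ViabilitySignalSpec", "SeedScene", "PlacementError", "render_scene",
    "default_homography", "embryo_ir_means", "FULL_RGB_SHAPE", "FULL_IR_SHAPE",
]

# full-scale sensor geometries (rows, cols)
FULL_RGB_SHAPE = (2048, 2448)
FULL_IR_SHAPE = (256, 320)

_BACKGROUND_RGB = 0.01   # flannel reflectance < 2%
_BACKGROUND_IR = 0.02
_BODY_IR = 0.55          # seed body infrared reflectance
_EMBRYO_IR_VIABLE = 0.78  # embryo-region intensity of a viable seed


class PlacementError(ValueError):
    """Raised when the requested rows cannot be placed in the frame."""


@dataclass(frozen=True)
class ViabilitySignalSpec:
    effect_size: float = 0.3      # embryo-mean IR drop for non-viable seeds
    embryo_fraction: float = 0.25  # fraction of seed area carrying the signal
    ir_noise_sd: float = 0.01     # per-pixel Gaussian noise on the IR frame

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.embryo_fraction < 1:
            raise ValueError("embryo_fraction must lie in (0, 1)")


@dataclass
class SeedScene:
    rgb_frame: np.ndarray          # (H_v, W_v, 3) in [0, 1]
    ir_frame: np.ndarray           # (H_i, W_i) in [0, 1]
    true_homography: np.ndarray    # 3x3, IR (x, y) -> RGB (x, y)
    boxes: np.ndarray              # (N, 4) [x0, y0, x1, y1], half-open, RGB px
    labels: list[tuple[str, str]]  # per-box (class_id, viability)
    rng_seed: int = 0
    scene_id: str = ""

    def __post_init__(self):
        if len(self.boxes) != len(self.labels):
            raise ValueError("boxes and labels disagree in length")


def default_homography(scale: float = 0.25) -> np.ndarray:
    """True IR->RGB homography for the synthetic rig.

    Dominated by the resolution ratio of the two sensors, with a small
    translation and mild projective terms standing in for mounting offset
    and lens perspective.  Column/row (x, y) convention.
    """
    h_v, w_v = (int(round(s * scale)) for s in FULL_RGB_SHAPE)
    h_i, w_i = (int(round(s * scale)) for s in FULL_IR_SHAPE)
    sx, sy = w_v / w_i, h_v / h_i
    H = np.array([
        [sx, 0.015 * sx, 1.2],
        [-0.010 * sy, sy, 0.8],
        [2.0e-5, -1.5e-5, 1.0],
    ])
    return H / H[2, 2]


@dataclass(frozen=True)
class _Placed:
    row: ManifestRow
    spec: SpeciesSpec
    cx: float
    cy: float
    a: float      # semi-major axis, RGB px
    b: float      # semi-minor axis
    theta: float  # orientation, radians


def _half_extents(a: float, b: float, theta: float) -> tuple[float, float]:
    """Axis-aligned half extents of a rotated ellipse."""
    ex = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    ey = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    return ex, ey


def _place_seeds(rows, table, layout, scale, shape, rng) -> list[_Placed]:
    h, w = shape
    by_id = {s.class_id: s for s in table}
    sizes = []
    specs = []
    for row in rows:
        if row.class_id not in by_id:
            raise KeyError(f"unknown class id {row.class_id}")
        spec = by_id[row.class_id]
        mean, sd = spec.size_px
        major = max(float(rng.normal(mean, sd)) * scale, 4.0)
        specs.append((spec, major))
        sizes.append(major)
    cell = max(sizes) + 14.0  # worst-case extent plus clearance (> closing reach)
    placed: list[_Placed] = []

    if layout == "grid":
        cols = int(w // cell)
        rows_fit = int(h // cell)
        if cols * rows_fit < len(rows):
            raise PlacementError(
                f"grid layout overflow: {len(rows)} seeds need more than "
                f"{cols * rows_fit} cells (first failing row: "
                f"{rows[cols * rows_fit].sample_id})")
        for i, (row, (spec, major)) in enumerate(zip(rows, specs)):
            r, c = divmod(i, cols)
            jx, jy = rng.uniform(-2.0, 2.0, size=2)
            cx = (c + 0.5) * cell + jx
            cy = (r + 0.5) * cell + jy
            # grid ground-truthing lays seeds roughly axis-aligned; only
            # modest orientation jitter remains
            theta = float(rng.uniform(-np.pi / 12, np.pi / 12))
            a = major / 2.0
            b = a / spec.ellipse_aspect
            placed.append(_Placed(row, spec, cx, cy, a, b, theta))
    elif layout == "poisson":
        # rejection-sampled dart throwing with a fixed iteration cap
        max_iter = 200
        for row, (spec, major) in zip(rows, specs):
            a = major / 2.0
            b = a / spec.ellipse_aspect
            theta = float(rng.uniform(-np.pi / 12, np.pi / 12))
            ex, ey = _half_extents(a, b, theta)
            ok = False
            for _ in range(max_iter):
                cx = rng.uniform(ex + 2, w - ex - 2)
                cy = rng.uniform(ey + 2, h - ey - 2)
                if all(np.hypot(cx - p.cx, cy - p.cy) > (cell + 2) for p in placed):
                    ok = True
                    break
            if not ok:
                raise PlacementError(
                    f"poisson layout: could not place row {row.sample_id}")
            placed.append(_Placed(row, spec, cx, cy, a, b, theta))
    else:
        raise ValueError(f"unknown layout {layout!r}")

    for p in placed:
        ex, ey = _half_extents(p.a, p.b, p.theta)
        if p.cx - ex < 0 or p.cy - ey < 0 or p.cx + ex > w or p.cy + ey > h:
            raise PlacementError(f"seed {p.row.sample_id} exceeds frame bounds")
    return placed


def _ellipse_field(p: _Placed, xx, yy) -> np.ndarray:
    """Normalised elliptical radius (<1 inside the seed) on the local patch."""
    dx, dy = xx - p.cx, yy - p.cy
    u = dx * np.cos(p.theta) + dy * np.sin(p.theta)
    v = -dx * np.sin(p.theta) + dy * np.cos(p.theta)
    return np.sqrt((u / p.a) ** 2 + (v / p.b) ** 2), u


def render_scene(manifest_rows: list[ManifestRow],
                 species_table: tuple[SpeciesSpec, ...] = DEFAULT_SPECIES,
                 viability_spec: ViabilitySignalSpec | None = None,
                 layout: str = "grid",
                 seed: int = 0,
                 scale: float = 0.25,
                 homography: np.ndarray | None = None,
                 rgb_viability_leak: float = 0.0) -> SeedScene:
    """Render one paired RGB/IR frame for the given manifest rows."""
    if viability_spec is None:
        viability_spec = ViabilitySignalSpec()
    H = default_homography(scale) if homography is None else np.asarray(homography)
    h_v, w_v = (int(round(s * scale)) for s in FULL_RGB_SHAPE)
    h_i, w_i = (int(round(s * scale)) for s in FULL_IR_SHAPE)

    rng = spawn(seed, "scene")
    placed = _place_seeds(manifest_rows, species_table, layout, scale,
                          (h_v, w_v), rng)

    rgb = np.full((h_v, w_v, 3), _BACKGROUND_RGB)
    ir_field = np.full((h_v, w_v), _BACKGROUND_IR)  # IR scene in RGB geometry
    boxes = np.zeros((len(placed), 4), dtype=np.int64)
    labels: list[tuple[str, str]] = []
    embryo_scale = np.sqrt(viability_spec.embryo_fraction)

    for i, p in enumerate(placed):
        ex, ey = _half_extents(p.a, p.b, p.theta)
        x0 = int(np.floor(p.cx - ex))
        y0 = int(np.floor(p.cy - ey))
        x1 = int(np.ceil(p.cx + ex)) + 1
        y1 = int(np.ceil(p.cy + ey)) + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w_v), min(y1, h_v)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        r, u = _ellipse_field(p, xx, yy)
        inside = r < 1.0

        color = np.clip(
            np.asarray(p.spec.base_color) + rng.normal(0.0, 0.02, size=3), 0, 1)
        viability = p.row.viability
        if rgb_viability_leak > 0.0 and viability == "non_viable":
            color = color * (1.0 - rgb_viability_leak)
        patch = np.zeros(inside.shape + (3,))
        patch[...] = color
        if p.spec.stripe_period > 0:
            period = max(p.spec.stripe_period * scale, 2.0)
            stripes = (np.sin(2.0 * np.pi * u / period) > 0).astype(float)
            patch += 0.28 * stripes[..., None]
        shading = 1.0 - 0.35 * np.clip(r, 0.0, 1.0) ** 2  # limb darkening
        patch *= shading[..., None]
        patch += rng.normal(0.0, 0.01, size=patch.shape)
        rgb[y0:y1, x0:x1][inside] = np.clip(patch, 0, 1)[inside]

        # infrared: uniform body plus concentric embryo region
        body = _BODY_IR + float(rng.normal(0.0, 0.01))
        embryo = _EMBRYO_IR_VIABLE
        if viability == "non_viable":
            embryo = embryo - viability_spec.effect_size
        ir_patch = np.where(r < embryo_scale, embryo, body)
        ir_field[y0:y1, x0:x1][inside] = ir_patch[inside]

        boxes[i] = (x0, y0, x1, y1)
        labels.append((p.spec.class_id, viability))

    # image the IR scene through the true homography at IR resolution
    tform = ProjectiveTransform(matrix=H)
    ir = warp(ir_field, tform, output_shape=(h_i, w_i), order=1,
              cval=_BACKGROUND_IR, preserve_range=True)
    ir = ir + spawn(seed, "ir-noise").normal(0.0, viability_spec.ir_noise_sd,
                                             size=ir.shape)
    ir = np.clip(ir, 0.0, 1.0)

    # boxes pairwise disjoint is guaranteed by placement; double-check cheaply
    _assert_disjoint(boxes)
    return SeedScene(rgb_frame=rgb, ir_frame=ir, true_homography=H,
                     boxes=boxes, labels=labels,
                     rng_seed=child_seed(seed, "scene"))


def _assert_disjoint(boxes: np.ndarray) -> None:
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            x0 = max(boxes[i, 0], boxes[j, 0])
            y0 = max(boxes[i, 1], boxes[j, 1])
            x1 = min(boxes[i, 2], boxes[j, 2])
            y1 = min(boxes[i, 3], boxes[j, 3])
            if x0 < x1 and y0 < y1:
                raise PlacementError(f"boxes {i} and {j} overlap")


def embryo_ir_means(scene: SeedScene,
                    embryo_fraction: float = 0.25) -> np.ndarray:
    """Per-seed mean IR intensity over the embryo region.

    Samples the IR frame at the embryo pixels of each ground-truth box,
    mapped through the inverse of the true homography.  Serves as the
    measurement behind the viability threshold oracle.
    """
    Hinv = np.linalg.inv(scene.true_homography)
    h_i, w_i = scene.ir_frame.shape
    means = np.zeros(len(scene.boxes))
    s = np.sqrt(embryo_fraction)
    for i, (x0, y0, x1, y1) in enumerate(scene.boxes):
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        # shrink the box around its centre to the embryo extent
        hx, hy = s * (x1 - x0) / 2.0, s * (y1 - y0) / 2.0
        yy, xx = np.mgrid[cy - hy:cy + hy:8j, cx - hx:cx + hx:8j]
        pts = np.stack([xx.ravel(), yy.ravel(), np.ones(xx.size)])
        ir_pts = Hinv @ pts
        ir_pts = ir_pts[:2] / ir_pts[2]
        cols = np.clip(np.round(ir_pts[0]).astype(int), 0, w_i - 1)
        rows = np.clip(np.round(ir_pts[1]).astype(int), 0, h_i - 1)
        means[i] = scene.ir_frame[rows, cols].mean()
    return means
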