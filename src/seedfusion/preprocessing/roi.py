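"""Region-of-interest extraction: one crop pair per seed.

Pipeline: luma conversion -> Otsu threshold -> morphological closing ->
connected components -> per-component bounding box expanded by a margin and
clipped to the frame -> synchronized crops of both modalities, resized to a
square sample.  Components smaller than ``min_area`` px are treated as
noise and discarded.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, footprint_rectangle
from skimage.transform import resize

__all__ = ["extract_rois", "rgb_to_luma", "box_iou"]

_LUMA = np.array([0.299, 0.587, 0.114])


def rgb_to_luma(rgb: np.ndarray) -> np.ndarray:
    return np.asarray(rgb, dtype=float) @ _LUMA


def box_iou(a, b) -> float:
    """Intersection-over-union of two half-open [x0, y0, x1, y1] boxes."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(ix1 - ix0, 0), max(iy1 - iy0, 0)
    inter = iw * ih
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def extract_rois(rgb_frame: np.ndarray, ir_registered: np.ndarray,
                 margin_px: int = 10, out_size: int = 224,
                 min_area: int = 25) -> list[tuple[np.ndarray, np.ndarray, tuple]]:
    """Detect seeds and crop both modalities with shared boxes.

    Returns a list of ``(rgb_crop, ir_crop, box)`` with crops resized to
    ``out_size`` and boxes as half-open (x0, y0, x1, y1) in frame pixels.
    An empty or seedless frame yields an empty list.
    """
    rgb = np.asarray(rgb_frame, dtype=float)
    ir = np.asarray(ir_registered, dtype=float)
    if rgb.shape[:2] != ir.shape[:2]:
        raise ValueError("rgb and registered IR frames must be aligned")
    h, w = rgb.shape[:2]
    luma = rgb_to_luma(rgb)
    if np.ptp(luma) < 1e-6:
        return []
    # Otsu in the log domain: against a near-black background the luma
    # histogram is background-heavy with a broad foreground (dark and
    # bright seed coats); log compression restores bimodality so the
    # threshold tracks the background/foreground split.
    log_luma = np.log(np.clip(luma, 1e-4, None))
    mask = log_luma > threshold_otsu(log_luma)
    mask = closing(mask, footprint_rectangle((5, 5)))
    out = []
    for region in regionprops(label(mask)):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        x0 = max(c0 - margin_px, 0)
        y0 = max(r0 - margin_px, 0)
        x1 = min(c1 + margin_px, w)
        y1 = min(r1 + margin_px, h)
        rgb_crop = resize(rgb[y0:y1, x0:x1], (out_size, out_size, 3),
                          anti_aliasing=True, preserve_range=True)
        ir_crop = resize(ir[y0:y1, x0:x1], (out_size, out_size),
                         anti_aliasing=True, preserve_range=True)
        out.append((rgb_crop, ir_crop, (x0, y0, x1, y1)))
    return out
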