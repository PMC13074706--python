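"""Intensity normalisation of cropped sample pairs.

RGB crops are scaled to [0, 1] and z-scored with the canonical ImageNet
channel statistics.  The single IR channel has no ImageNet statistics; it
is standardised with dataset-level mean/std (computed once from a training
split, with a documented fallback for unit-scale synthetic data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IMAGENET_MEAN", "IMAGENET_STD", "IR_FALLBACK_MEAN",
           "IR_FALLBACK_STD", "SeedSample", "to_unit_range",
           "normalize_sample", "denormalize_sample", "ir_statistics"]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])
IR_FALLBACK_MEAN = 0.5
IR_FALLBACK_STD = 0.25


@dataclass
class SeedSample:
    """One registered, cropped, normalised RGB+IR pair with labels."""
    rgb: np.ndarray                 # (S, S, 3), standardised
    ir: np.ndarray                  # (S, S), standardised
    class_id: str = ""
    viability: str = ""             # "viable" | "non_viable"
    source_box: tuple = (0, 0, 0, 0)
    scene_id: str = ""
    sample_id: str = ""
    normalized: bool = True


def to_unit_range(img: np.ndarray) -> np.ndarray:
    """Scale 8/16-bit integer or float imagery to [0, 1]."""
    arr = np.asarray(img)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite pixel values")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def ir_statistics(ir_crops: list[np.ndarray]) -> tuple[float, float]:
    """Dataset-level IR mean/std from a training split."""
    stacked = np.concatenate([np.ravel(to_unit_range(c)) for c in ir_crops])
    return float(stacked.mean()), float(max(stacked.std(), 1e-6))


def normalize_sample(rgb_crop: np.ndarray, ir_crop: np.ndarray,
                     ir_mean: float = IR_FALLBACK_MEAN,
                     ir_std: float = IR_FALLBACK_STD,
                     ) -> tuple[np.ndarray, np.ndarray]:
    rgb = (to_unit_range(rgb_crop) - IMAGENET_MEAN) / IMAGENET_STD
    ir = (to_unit_range(ir_crop) - ir_mean) / ir_std
    return rgb, ir


def denormalize_sample(rgb: np.ndarray, ir: np.ndarray,
                       ir_mean: float = IR_FALLBACK_MEAN,
                       ir_std: float = IR_FALLBACK_STD,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Algebraic inverse of :func:`normalize_sample` (unit-range output)."""
    return rgb * IMAGENET_STD + IMAGENET_MEAN, ir * ir_std + ir_mean
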