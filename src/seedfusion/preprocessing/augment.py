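"""Synchronized dual-modal augmentation.

One geometric transform (flips, rotation, isotropic scale) is sampled per
pair and applied identically to the RGB and IR crops, so cross-modal
alignment survives augmentation.  Photometric jitter is modality-specific:
brightness/contrast on RGB only, zero-mean Gaussian noise on IR only.
Labels are never touched; the sampled parameters are returned for logging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

__all__ = ["AugmentationConfig", "augment_pair"]


@dataclass(frozen=True)
class AugmentationConfig:
    p_flip: float = 0.5
    rotation_deg: float = 15.0          # symmetric range +-rotation_deg
    scale_range: tuple[float, float] = (0.8, 1.2)
    color_jitter_frac: float = 0.10     # +-10% brightness and contrast
    ir_noise_sd: float = 0.01
    enabled: bool = True
    interpolation_order: int = 1        # bilinear; 0 = nearest (for masks)

    def __post_init__(self):
        if not 0.0 <= self.p_flip <= 1.0:
            raise ValueError("p_flip must be a probability")
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be (low, high)")


def _centered_affine(angle_rad: float, scale: float, shape) -> AffineTransform:
    h, w = shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t = AffineTransform(rotation=angle_rad, scale=(scale, scale))
    offset = center - t.params[:2, :2] @ center
    return AffineTransform(rotation=angle_rad, scale=(scale, scale),
                           translation=offset)


def augment_pair(rgb: np.ndarray, ir: np.ndarray, config: AugmentationConfig,
                 rng: np.random.Generator):
    """Apply one synchronized augmentation; returns (rgb', ir', params)."""
    rgb = np.asarray(rgb, dtype=float)
    ir = np.asarray(ir, dtype=float)
    if rgb.shape[:2] != ir.shape[:2]:
        raise ValueError("rgb and ir must share spatial shape")
    if not config.enabled:
        return rgb, ir, {"enabled": False}

    flip_h = bool(rng.random() < config.p_flip)
    flip_v = bool(rng.random() < config.p_flip)
    angle = float(rng.uniform(-config.rotation_deg, config.rotation_deg))
    scale = float(rng.uniform(*config.scale_range))
    brightness = 1.0 + float(rng.uniform(-config.color_jitter_frac,
                                         config.color_jitter_frac))
    contrast = 1.0 + float(rng.uniform(-config.color_jitter_frac,
                                       config.color_jitter_frac))
    params = {"enabled": True, "flip_h": flip_h, "flip_v": flip_v,
              "rotation_deg": angle, "scale": scale,
              "brightness": brightness, "contrast": contrast}

    if flip_h:
        rgb, ir = rgb[:, ::-1], ir[:, ::-1]
    if flip_v:
        rgb, ir = rgb[::-1], ir[::-1]

    if abs(angle) > 1e-12 or abs(scale - 1.0) > 1e-12:
        tform = _centered_affine(np.deg2rad(angle), scale, rgb.shape)
        inv = AffineTransform(matrix=np.linalg.inv(tform.params))
        order = config.interpolation_order
        rgb = warp(rgb, inv, order=order, mode="reflect", preserve_range=True)
        ir = warp(ir, inv, order=order, mode="reflect", preserve_range=True)

    if config.color_jitter_frac > 0:
        mean = rgb.mean()
        rgb = np.clip((rgb * brightness - mean) * contrast + mean, 0.0, 1.0)
    if config.ir_noise_sd > 0:
        ir = ir + rng.normal(0.0, config.ir_noise_sd, size=ir.shape)
    return rgb, ir, params
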