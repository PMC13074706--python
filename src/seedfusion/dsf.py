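"""Dual-Spectral Fusion (DSF).

The infrared branch runs a compact convolutional backbone and refines its
feature map with CBAM-style channel-then-spatial gating:

    Mc = sigmoid(MLP(AvgPool(F)) + MLP(MaxPool(F)))   (shared MLP)
    F' = Mc (x) F
    Ms = sigmoid(Conv7x7([AvgPool_c(F'); MaxPool_c(F')]))
    F_att = Ms (x) F'

Both gates are sigmoid outputs, so refinement only ever attenuates.  The
visible branch aggregates textures at four receptive fields (1/3/5/7 px
kernels) and fuses them with a 1x1 reduction and ReLU.  Ternary fusion
global-average-pools both maps to vectors, concatenates them with the
semantic residual from the alignment module, and maps through an MLP to
the fused feature ``Fs`` used for viability discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import spawn
from .nn import (Tensor, Module, Linear, Conv2d, GELU, ReLU, Sequential,
                 concat, global_avg_pool, global_max_pool)

__all__ = ["IRBackbone", "VisStem", "CBAM", "MultiScaleAggregate",
           "FusionMLP", "FusedFeature"]


class IRBackbone(Module):
    """Compact convolutional backbone for the single-channel IR crop."""

    def __init__(self, channels: int = 16, seed: int = 0, in_channels: int = 1):
        rng = spawn(seed, "ir-backbone")
        self.conv1 = Conv2d(in_channels, channels, kernel=3, rng=rng, stride=2)
        self.conv2 = Conv2d(channels, channels, kernel=3, rng=rng, stride=2)
        self.in_channels = in_channels
        self.channels = channels

    def forward(self, ir: np.ndarray | Tensor) -> Tensor:
        """(B, S, S) or (B, S, S, C) -> (B, C, S/4, S/4) feature map."""
        if not isinstance(ir, Tensor):
            x = np.asarray(ir, dtype=np.float64)
            if x.ndim == 3:
                x = x[:, None]  # (B, 1, S, S)
            else:
                x = x.transpose(0, 3, 1, 2)
            ir = Tensor(x)
        if ir.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {ir.shape[1]}")
        return self.conv2(self.conv1(ir).relu()).relu()


class VisStem(Module):
    """Two-conv stem producing the visible feature map Fvis."""

    def __init__(self, channels: int = 16, seed: int = 0, in_channels: int = 3):
        rng = spawn(seed, "vis-stem")
        self.conv1 = Conv2d(in_channels, channels, kernel=3, rng=rng, stride=2)
        self.conv2 = Conv2d(channels, channels, kernel=3, rng=rng, stride=2)
        self.in_channels = in_channels
        self.channels = channels

    def forward(self, rgb: np.ndarray | Tensor) -> Tensor:
        if not isinstance(rgb, Tensor):
            x = np.asarray(rgb, dtype=np.float64).transpose(0, 3, 1, 2)
            rgb = Tensor(np.ascontiguousarray(x))
        if rgb.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {rgb.shape[1]}")
        return self.conv2(self.conv1(rgb).relu()).relu()


class CBAM(Module):
    """Channel + spatial attention gates (sequential, sigmoid-bounded)."""

    def __init__(self, channels: int, reduction: int = 4, seed: int = 0):
        rng = spawn(seed, "cbam")
        hidden = max(channels // reduction, 2)
        self.mlp = Sequential(Linear(channels, hidden, rng), ReLU(),
                              Linear(hidden, channels, rng))
        self.spatial_conv = Conv2d(2, 1, kernel=7, rng=rng, padding=3)
        self.channels = channels

    def forward(self, fir: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        if fir.shape[1] != self.channels:
            raise ValueError("channel count mismatch")
        b, c = fir.shape[:2]
        avg = global_avg_pool(fir)            # (B, C)
        mx = global_max_pool(fir)             # (B, C)
        mc = (self.mlp(avg) + self.mlp(mx)).sigmoid()          # (B, C)
        fir_p = fir * mc.reshape(b, c, 1, 1)
        s_avg = fir_p.mean(axis=1, keepdims=True)              # (B, 1, H, W)
        s_max = fir_p.max(axis=1, keepdims=True)
        ms = self.spatial_conv(concat([s_avg, s_max], axis=1)).sigmoid()
        fir_att = fir_p * ms
        return fir_att, mc, ms


class MultiScaleAggregate(Module):
    """Parallel 1/3/5/7 px convolutions, concat, 1x1 reduction, ReLU."""

    KERNELS = (1, 3, 5, 7)

    def __init__(self, channels: int = 16, branch_channels: int | None = None,
                 seed: int = 0, preconv: bool = True):
        rng = spawn(seed, "multiscale")
        if branch_channels is None:
            branch_channels = max(channels // 2, 1)
        self.pre = (Conv2d(channels, channels, kernel=3, rng=rng)
                    if preconv else None)
        self.branches = [Conv2d(channels, branch_channels, kernel=k, rng=rng)
                         for k in self.KERNELS]
        self.reduce = Conv2d(branch_channels * len(self.KERNELS), channels,
                             kernel=1, rng=rng)
        self.channels = channels

    def forward(self, fvis: Tensor) -> Tensor:
        x = self.pre(fvis).relu() if self.pre is not None else fvis
        feats = [branch(x) for branch in self.branches]
        return self.reduce(concat(feats, axis=1)).relu()


@dataclass
class FusedFeature:
    fs: Tensor                       # (B, d_fuse) fused vector
    branch_vectors: tuple            # (pooled Firatt, pooled Fvisms, Fres)


class FusionMLP(Module):
    """Ternary fusion head: GAP both maps, concat with Fres, MLP."""

    def __init__(self, c_ir: int, c_vis: int, d_sem: int, d_fuse: int = 32,
                 seed: int = 0):
        rng = spawn(seed, "fusion")
        in_dim = c_ir + c_vis + d_sem
        self.net = Sequential(Linear(in_dim, 2 * d_fuse, rng), GELU(),
                              Linear(2 * d_fuse, d_fuse, rng))
        self.c_ir, self.c_vis = c_ir, c_vis
        self.in_dim, self.d_fuse = in_dim, d_fuse

    def forward(self, fir_att: Tensor | None, fvis_ms: Tensor | None,
                fres: Tensor) -> FusedFeature:
        """Spatial inputs may be None (ablation): zero vectors are substituted."""
        b = fres.shape[0]
        pooled_ir = (global_avg_pool(fir_att) if fir_att is not None
                     else Tensor(np.zeros((b, self.c_ir))))
        pooled_vis = (global_avg_pool(fvis_ms) if fvis_ms is not None
                      else Tensor(np.zeros((b, self.c_vis))))
        parts = [pooled_ir, pooled_vis, fres]
        cat = concat(parts, axis=1)
        if cat.shape[1] != self.in_dim:
            raise ValueError(
                f"fusion expects width {self.in_dim}, got {cat.shape[1]}")
        fs = self.net(cat)
        return FusedFeature(fs=fs, branch_vectors=(pooled_ir, pooled_vis, fres))
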