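"""Joint-Learning Head (JLH).

Species identity is predicted metrically: the semantically enhanced
feature is compared by cosine similarity against a bank of per-class text
prototypes, so adding a class needs no new parameters.  Viability is
predicted distributionally: a small MLP plus projection on the fused
feature outputs a 2-way softmax.  The two tasks are balanced by

    L_total = lambda * L_cls + (1 - lambda) * L_via   (lambda = 0.6)

optionally extended with the contrastive alignment term.  Cosine scores
live in [-1, 1], which makes a plain softmax nearly uniform; they are
therefore temperature-scaled before the cross-entropy (shared with the
contrastive temperature by default, raw cosines available by config).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import spawn
from .nn import (Tensor, Module, Linear, GELU, Sequential, softmax,
                 cross_entropy, l2_normalize, global_avg_pool)

__all__ = ["ClassPrototypeBank", "Prediction", "LossBundle", "match_scores",
           "species_loss", "ViabilityHead", "total_loss", "DEFAULT_LAMBDA"]

DEFAULT_LAMBDA = 0.6


@dataclass
class ClassPrototypeBank:
    """L2-normalised per-class text embeddings, one row per class."""
    wtext: Tensor            # (K, d), rows unit-norm
    class_ids: list[str]

    def __post_init__(self):
        norms = np.linalg.norm(self.wtext.data, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("prototype rows must be L2-normalised")
        if self.wtext.shape[0] != len(self.class_ids):
            raise ValueError("one class id per prototype row")

    @property
    def k(self) -> int:
        return len(self.class_ids)


@dataclass
class Prediction:
    match_scores: np.ndarray     # (K,) cosine similarities in [-1, 1]
    species_pred: str
    p_via: np.ndarray            # (2,) (viable, non_viable) on the simplex
    viability_pred: str


def match_scores(fsem: Tensor, bank: ClassPrototypeBank) -> Tensor:
    """Cosine similarity of each sample against every class prototype."""
    norms = np.linalg.norm(fsem.data, axis=-1)
    if np.any(norms <= 0):
        raise ValueError("zero-norm semantic feature")
    return l2_normalize(fsem) @ bank.wtext.T


def species_loss(scores: Tensor, true_class: np.ndarray,
                 logit_scale: float | Tensor = 1.0) -> Tensor:
    """Cross-entropy of softmax(logit_scale * cosine scores)."""
    if not np.all(np.isfinite(scores.data)):
        raise ValueError("non-finite match scores")
    logits = scores * logit_scale
    return cross_entropy(logits, true_class)


class ViabilityHead(Module):
    """GAP (upstream) -> two MLP layers -> linear projection -> softmax."""

    def __init__(self, in_dim: int, hidden: tuple[int, int] = (32, 16),
                 seed: int = 0):
        rng = spawn(seed, "viability-head")
        h1, h2 = hidden
        self.net = Sequential(Linear(in_dim, h1, rng), GELU(),
                              Linear(h1, h2, rng), GELU())
        self.project = Linear(h2, 2, rng)
        self.in_dim = in_dim

    def logits(self, fs: Tensor) -> Tensor:
        if fs.ndim == 4:  # spatial fused feature: pool here
            fs = global_avg_pool(fs)
        return self.project(self.net(fs))

    def forward(self, fs: Tensor) -> Tensor:
        """Probability simplex over (viable, non_viable)."""
        return softmax(self.logits(fs), axis=-1)


@dataclass
class LossBundle:
    lcls: Tensor | float
    lvia: Tensor | float
    lam: float = DEFAULT_LAMBDA
    lcon: Tensor | float | None = None
    w_con: float = 0.0


def total_loss(bundle: LossBundle) -> Tensor | float:
    """Weighted multi-task objective lambda*Lcls + (1-lambda)*Lvia [+ w*Lcon]."""
    if not 0.0 <= bundle.lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    out = bundle.lcls * bundle.lam + bundle.lvia * (1.0 - bundle.lam)
    if bundle.lcon is not None and bundle.w_con != 0.0:
        out = out + bundle.lcon * bundle.w_con
    return out
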