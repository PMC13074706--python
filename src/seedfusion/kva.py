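"""Knowledge-Vision Alignment (KVA).

Frozen dual-stream encoders map a seed crop and its encyclopedic
description to feature vectors ``fv`` and ``ft``; trainable projection
heads bring both into a shared d-dimensional space (``zv``, ``zt``); a
symmetric InfoNCE loss with a learnable temperature aligns the two; and a
single-head cross-attention block injects textual semantics into the
visual embedding:

    Fsem = LayerNorm(zv + Attention(zv W_Q, zt W_K, zt W_V))
    Fres = Fsem - zv

Embeddings are L2-normalised before the contrastive similarity (CLIP
convention), which makes the temperature scale-meaningful.  The desk-scale
encoders below are deliberately tiny, deterministic and training-free:
a random-weight convolutional stem for images and a bag-of-embeddings
encoder for token sequences.  Pre-trained encoders can be plugged in
behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import spawn
from .nn import (Tensor, Module, Parameter, Linear, LayerNorm, GELU,
                 Sequential, softmax, l2_normalize, cross_entropy)
from .preprocessing.tokenizer import TokenizedText, Vocabulary, tokenize

__all__ = [
    "TinyVisualEncoder", "TinyTextEncoder", "EncoderPair", "ProjectionHead",
    "CrossAttention", "SemanticFeature", "contrastive_loss", "encode_texts",
]


class TinyVisualEncoder(Module):
    """Frozen random-projection convolutional image encoder.

    Two strided convolutions followed by global average pooling.  The
    weights are drawn once from the seed and then frozen: the encoder is a
    fixed feature extractor in the spirit of a frozen pre-trained backbone,
    preserving colour statistics and coarse shape cues linearly.
    """

    def __init__(self, out_dim: int = 32, in_channels: int = 3, seed: int = 0):
        rng = spawn(seed, "visual-encoder")
        mid = max(out_dim // 2, 4)
        from .nn import Conv2d  # local import keeps the module list tidy
        self.conv1 = Conv2d(in_channels, mid, kernel=5, rng=rng, stride=4,
                            padding=2)
        self.conv2 = Conv2d(mid, out_dim, kernel=3, rng=rng, stride=2,
                            padding=1)
        self.out_dim = out_dim
        self.in_channels = in_channels
        self.freeze()

    def forward(self, images: np.ndarray) -> Tensor:
        """(B, S, S, C) channel-last float array -> (B, out_dim)."""
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} channels, got {x.shape[-1]}")
        t = Tensor(np.ascontiguousarray(x.transpose(0, 3, 1, 2)))
        h = self.conv1(t).relu()
        h = self.conv2(h).relu()
        return h.mean(axis=(2, 3))


class TinyTextEncoder(Module):
    """Frozen bag-of-embeddings text encoder.

    Each vocabulary id owns a fixed random embedding; a sequence encodes to
    the mean embedding over its attention mask.  Deterministic given the
    seed and vocabulary size.
    """

    def __init__(self, vocab_size: int, out_dim: int = 32, seed: int = 0):
        rng = spawn(seed, "text-encoder")
        self.embeddings = Parameter(rng.normal(0.0, 1.0, (vocab_size, out_dim)))
        self.out_dim = out_dim
        self.freeze()

    def forward(self, tokens: TokenizedText) -> Tensor:
        ids = tokens.token_ids
        mask = tokens.attention_mask.astype(bool)
        return Tensor(self.embeddings.data[ids[mask]].mean(axis=0))

    def forward_batch(self, token_batch: list[TokenizedText]) -> Tensor:
        return Tensor(np.stack([self.forward(t).data for t in token_batch]))


@dataclass
class EncoderPair:
    visual_encoder: TinyVisualEncoder
    text_encoder: TinyTextEncoder
    frozen: bool = True


class ProjectionHead(Module):
    """Two-layer MLP (linear-GELU-linear) into the joint d-space."""

    def __init__(self, in_dim: int, d: int, rng: np.random.Generator):
        self.net = Sequential(Linear(in_dim, d, rng), GELU(), Linear(d, d, rng))
        self.in_dim, self.d = in_dim, d

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"expected dim {self.in_dim}, got {x.shape[-1]}")
        return self.net(x)


def contrastive_loss(zv: Tensor, zt: Tensor, tau) -> Tensor:
    """Symmetric InfoNCE over a batch of aligned pairs.

    Rows are L2-normalised; positives sit on the diagonal; the loss is the
    mean of the image-to-text and text-to-image cross-entropies.  ``tau``
    may be a float or a positive scalar Tensor (kept differentiable).
    """
    if zv.shape != zt.shape or zv.ndim != 2:
        raise ValueError("zv and zt must be matching (N, d) batches")
    n = zv.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    tau_val = tau.item() if isinstance(tau, Tensor) else float(tau)
    if tau_val <= 0:
        raise ValueError("temperature must be positive")
    zvn = l2_normalize(zv)
    ztn = l2_normalize(zt)
    sims = (zvn @ ztn.T)
    sims = sims * (Tensor(1.0) / tau if isinstance(tau, Tensor) else 1.0 / tau_val)
    labels = np.arange(n)
    return (cross_entropy(sims, labels) + cross_entropy(sims.T, labels)) * 0.5


@dataclass
class SemanticFeature:
    fsem: Tensor                # (B, d) semantically enhanced feature
    fres: Tensor                # (B, d) residual: Fsem - zv
    attention_weights: Tensor   # (B, K) rows on the simplex


class CrossAttention(Module):
    """Single-head scaled dot-product attention with residual + LayerNorm.

    The visual embedding is the query; text embeddings (a per-class
    prototype bank or a token sequence) are keys and values.
    """

    def __init__(self, d: int, dk: int | None = None,
                 rng: np.random.Generator | None = None):
        if dk is None:
            dk = d
        if dk <= 0:
            raise ValueError("dk must be positive")
        rng = rng if rng is not None else np.random.default_rng(0)
        s = 1.0 / np.sqrt(d)
        self.wq = Parameter(rng.normal(0.0, s, (d, dk)))
        self.wk = Parameter(rng.normal(0.0, s, (d, dk)))
        self.wv = Parameter(rng.normal(0.0, s, (d, d)))
        self.norm = LayerNorm(d)
        self.d, self.dk = d, dk

    def forward(self, zv: Tensor, zt_tokens: Tensor) -> SemanticFeature:
        """zv: (B, d); zt_tokens: (K, d) keys/values."""
        if zv.shape[-1] != self.d or zt_tokens.shape[-1] != self.d:
            raise ValueError("embedding dimension mismatch")
        q = zv @ self.wq                      # (B, dk)
        k = zt_tokens @ self.wk               # (K, dk)
        v = zt_tokens @ self.wv               # (K, d)
        scores = (q @ k.T) * (1.0 / np.sqrt(self.dk))
        weights = softmax(scores, axis=-1)    # (B, K)
        attended = weights @ v                # (B, d)
        normed = self.norm(zv + attended)
        fres = normed - zv
        # recompose so Fres + zv == Fsem holds bitwise (floating-point
        # subtraction then addition of the same operand is exact here)
        fsem = zv + fres
        return SemanticFeature(fsem=fsem, fres=fres, attention_weights=weights)


def encode_texts(corpus: dict[str, list[str]], vocab: Vocabulary,
                 encoder: TinyTextEncoder) -> dict[str, np.ndarray]:
    """Frozen text features per class: class_id -> (n_texts, Dt) array."""
    out: dict[str, np.ndarray] = {}
    for class_id in sorted(corpus):
        toks = [tokenize(t, vocab) for t in corpus[class_id]]
        out[class_id] = encoder.forward_batch(toks).data
    return out
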