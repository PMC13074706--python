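"""The full semantic-spectral seed network.

Composes the three blocks — knowledge-vision alignment (KVA), dual-spectral
fusion (DSF) and the joint-learning head (JLH) — into one trainable model
with switchable fusion strategies (visible-only, infrared-only, early,
late, ternary) and component ablations (full, no-KVA, no-DSF, baseline),
all sharing the same data path so ablations are paired.

Desk-scale defaults favour CPU runtime: 64 px crops, 16-channel conv
branches and a 32-dimensional joint space.  All widths are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._rng import spawn
from .nn import (Tensor, Module, Parameter, Linear, Conv2d, no_grad, softmax,
                 cross_entropy)
from .kva import (TinyVisualEncoder, TinyTextEncoder, EncoderPair,
                  ProjectionHead, CrossAttention, contrastive_loss,
                  encode_texts)
from .dsf import IRBackbone, VisStem, CBAM, MultiScaleAggregate, FusionMLP
from .jlh import (ClassPrototypeBank, LossBundle, ViabilityHead, match_scores,
                  species_loss, total_loss, DEFAULT_LAMBDA)
from .nn import l2_normalize
from .preprocessing.tokenizer import Vocabulary

__all__ = ["ModelConfig", "SeedFusionNet", "FUSION_MODES", "COMPONENT_MODES"]

FUSION_MODES = ("ternary", "rgb_only", "ir_only", "early", "late")
COMPONENT_MODES = ("full", "no_kva", "no_dsf", "baseline")


@dataclass(frozen=True)
class ModelConfig:
    crop_size: int = 64
    dv: int = 32                 # frozen visual feature width
    dt: int = 32                 # frozen text feature width
    d: int = 32                  # joint embedding width
    dk: int = 32                 # attention key width
    c_ir: int = 16               # IR branch channels
    c_vis: int = 16              # visible branch channels
    d_fuse: int = 32             # fused feature width
    lam: float = DEFAULT_LAMBDA  # species/viability balance
    w_con: float = 1.0           # contrastive co-training weight
    tau_init: float = 0.07       # contrastive temperature init
    fusion_mode: str = "ternary"
    component_mode: str = "full"
    logit_scale_mode: str = "tau"  # "tau" shares 1/tau; "raw" uses cosines
    seed: int = 0

    def __post_init__(self):
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion_mode!r}")
        if self.component_mode not in COMPONENT_MODES:
            raise ValueError(f"unknown component mode {self.component_mode!r}")

    def with_mode(self, fusion_mode: str | None = None,
                  component_mode: str | None = None) -> "ModelConfig":
        kwargs = {}
        if fusion_mode is not None:
            kwargs["fusion_mode"] = fusion_mode
        if component_mode is not None:
            kwargs["component_mode"] = component_mode
        return replace(self, **kwargs)


_TAU_BOUNDS = (1e-3, 100.0)


class SeedFusionNet(Module):
    """Joint species/viability model over registered RGB+IR seed crops."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary,
                 corpus: dict[str, list[str]]):
        cfg = config
        self.config = cfg
        self.class_ids = sorted(corpus)
        rng = spawn(cfg.seed, "model")

        # frozen encoders (KVA dual stream)
        self.visual_encoder = TinyVisualEncoder(cfg.dv, in_channels=3,
                                                seed=cfg.seed)
        self.text_encoder = TinyTextEncoder(len(vocab), cfg.dt, seed=cfg.seed)
        self.encoders = EncoderPair(self.visual_encoder, self.text_encoder)

        # trainable projection heads, attention, temperature
        self.proj_v = ProjectionHead(cfg.dv, cfg.d, spawn(cfg.seed, "proj-v"))
        self.proj_t = ProjectionHead(cfg.dt, cfg.d, spawn(cfg.seed, "proj-t"))
        self.cross_attn = CrossAttention(cfg.d, cfg.dk,
                                         spawn(cfg.seed, "attn"))
        self.log_tau = Parameter(np.log(cfg.tau_init))

        # DSF branches
        self.ir_backbone = IRBackbone(cfg.c_ir, seed=cfg.seed)
        self.vis_stem = VisStem(cfg.c_vis, seed=cfg.seed)
        self.early_stem = _EarlyStem(cfg.c_vis, seed=cfg.seed)
        self.cbam = CBAM(cfg.c_ir, seed=cfg.seed)
        self.multiscale = MultiScaleAggregate(cfg.c_vis, seed=cfg.seed)
        self.fusion = FusionMLP(cfg.c_ir, cfg.c_vis, cfg.d, cfg.d_fuse,
                                seed=cfg.seed)

        # JLH
        self.via_head = ViabilityHead(cfg.d_fuse, seed=cfg.seed)
        # class-sized linear head, used only when KVA is ablated
        self.species_linear = Linear(cfg.d_fuse, len(self.class_ids),
                                     spawn(cfg.seed, "species-linear"))

        # frozen per-class text features (n_classes kept open-ended)
        self._text_features = encode_texts(corpus, vocab, self.text_encoder)
        counts = [len(self._text_features[c]) for c in self.class_ids]
        self._ft_all = np.concatenate(
            [self._text_features[c] for c in self.class_ids])
        group = np.zeros((len(self.class_ids), self._ft_all.shape[0]))
        start = 0
        for i, n in enumerate(counts):
            group[i, start:start + n] = 1.0 / n
            start += n
        self._group = group

    # -- temperature -------------------------------------------------------
    @property
    def tau(self) -> Tensor:
        return self.log_tau.exp()

    def clamp_tau(self) -> None:
        lo, hi = np.log(_TAU_BOUNDS[0]), np.log(_TAU_BOUNDS[1])
        self.log_tau.data = np.clip(self.log_tau.data, lo, hi)

    # -- feature paths -----------------------------------------------------
    def text_prototypes(self) -> Tensor:
        """(K, d) projected per-class prototype means (trainable path)."""
        zt_all = self.proj_t(Tensor(self._ft_all))
        return Tensor(self._group) @ zt_all

    def _kva_features(self, rgb: np.ndarray, ir: np.ndarray,
                      prototypes: Tensor):
        cfg = self.config
        if cfg.fusion_mode == "ir_only":
            vis_input = np.repeat(ir[..., None], 3, axis=-1)
        else:
            vis_input = rgb
        fv = self.visual_encoder(vis_input)
        zv = self.proj_v(fv)
        sem = self.cross_attn(zv, prototypes)
        return zv, sem

    def forward_features(self, rgb: np.ndarray, ir: np.ndarray) -> dict:
        """All named intermediate features for a batch."""
        cfg = self.config
        b = rgb.shape[0]
        feats: dict[str, object] = {}

        kva_on = cfg.component_mode in ("full", "no_dsf")
        prototypes = self.text_prototypes()
        feats["prototypes"] = prototypes

        if kva_on:
            zv, sem = self._kva_features(rgb, ir, prototypes)
            feats.update(zv=zv, fsem=sem.fsem, fres=sem.fres,
                         attention=sem.attention_weights)
            fres = sem.fres
        else:
            fres = Tensor(np.zeros((b, cfg.d)))
            feats["fres"] = fres

        mode = cfg.fusion_mode
        if cfg.component_mode in ("no_dsf", "baseline"):
            mode = "rgb_only"

        fir_att = fvis_ms = None
        if mode == "early":
            stacked = np.concatenate([rgb, ir[..., None]], axis=-1)
            m = self.early_stem(stacked)
            fir_att, mc, ms = self.cbam(_match_channels(m, self.config.c_ir))
            fvis_ms = self.multiscale(m)
            feats.update(mc=mc, ms=ms)
        else:
            if mode in ("ternary", "ir_only", "late"):
                fir = self.ir_backbone(ir)
                fir_att, mc, ms = self.cbam(fir)
                feats.update(fir=fir, mc=mc, ms=ms)
            if mode in ("ternary", "rgb_only", "late"):
                fvis = self.vis_stem(rgb)
                fvis_ms = self.multiscale(fvis)
                feats.update(fvis=fvis, fvisms=fvis_ms)

        if mode == "late":
            fused_vis = self.fusion(None, fvis_ms, fres)
            fused_ir = self.fusion(fir_att, None, fres)
            feats.update(fs_vis=fused_vis.fs, fs_ir=fused_ir.fs)
        elif mode == "rgb_only":
            feats["fs"] = self.fusion(None, fvis_ms, fres).fs
        elif mode == "ir_only":
            feats["fs"] = self.fusion(fir_att, None, fres).fs
        else:  # ternary / early
            feats["fs"] = self.fusion(fir_att, fvis_ms, fres).fs
        if fir_att is not None:
            feats["firatt"] = fir_att
        return feats

    # -- heads -------------------------------------------------------------
    def _species_scores(self, feats: dict) -> Tensor:
        if self.config.component_mode in ("no_kva", "baseline"):
            fs = feats["fs"] if "fs" in feats else feats["fs_vis"]
            return self.species_linear(fs)
        bank = ClassPrototypeBank(l2_normalize(feats["prototypes"]),
                                  self.class_ids)
        return match_scores(feats["fsem"], bank)

    def _via_probs(self, feats: dict) -> Tensor:
        if "fs" in feats:
            return self.via_head(feats["fs"])
        # late fusion: decision-level averaging of per-modality softmaxes
        return (self.via_head(feats["fs_vis"]) +
                self.via_head(feats["fs_ir"])) * 0.5

    def _via_loss(self, feats: dict, via_idx: np.ndarray) -> Tensor:
        if "fs" in feats:
            return cross_entropy(self.via_head.logits(feats["fs"]), via_idx)
        probs = self._via_probs(feats)
        n = probs.shape[0]
        onehot = np.zeros(probs.shape)
        onehot[np.arange(n), via_idx] = 1.0
        return -((probs + 1e-12).log() * Tensor(onehot)).sum() * (1.0 / n)

    # -- training objective -------------------------------------------------
    def loss(self, rgb: np.ndarray, ir: np.ndarray, species_idx: np.ndarray,
             via_idx: np.ndarray) -> tuple[Tensor, dict]:
        cfg = self.config
        feats = self.forward_features(rgb, ir)
        scores = self._species_scores(feats)
        metric_head = cfg.component_mode in ("full", "no_dsf")
        if metric_head and cfg.logit_scale_mode == "tau":
            lcls = species_loss(scores, species_idx,
                                Tensor(1.0) / self.tau)
        else:
            lcls = species_loss(scores, species_idx, 1.0)
        lvia = self._via_loss(feats, via_idx)
        lcon = None
        if metric_head and cfg.w_con != 0.0:
            zt_pos = feats["prototypes"][species_idx]
            lcon = contrastive_loss(feats["zv"], zt_pos, self.tau)
        bundle = LossBundle(lcls=lcls, lvia=lvia, lam=cfg.lam, lcon=lcon,
                            w_con=cfg.w_con if lcon is not None else 0.0)
        ltotal = total_loss(bundle)
        parts = {"total": ltotal.item(), "cls": lcls.item(),
                 "via": lvia.item()}
        if lcon is not None:
            parts["con"] = lcon.item()
        return ltotal, parts

    # -- inference ---------------------------------------------------------
    def predict(self, rgb: np.ndarray, ir: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample species scores (B, K) and viability probs (B, 2)."""
        with no_grad():
            feats = self.forward_features(rgb, ir)
            scores = self._species_scores(feats).data
            pvia = self._via_probs(feats).data
        return scores, pvia

    def predict_labels(self, rgb: np.ndarray, ir: np.ndarray
                       ) -> tuple[list[str], list[str]]:
        scores, pvia = self.predict(rgb, ir)
        species = [self.class_ids[i] for i in scores.argmax(axis=1)]
        via = ["viable" if p[0] >= p[1] else "non_viable" for p in pvia]
        return species, via


class _EarlyStem(Module):
    """Widened 4-channel stem for input-level (early) fusion."""

    def __init__(self, channels: int, seed: int = 0):
        rng = spawn(seed, "early-stem")
        self.conv1 = Conv2d(4, channels, kernel=3, rng=rng, stride=2)
        self.conv2 = Conv2d(channels, channels, kernel=3, rng=rng, stride=2)

    def forward(self, x: np.ndarray) -> Tensor:
        t = Tensor(np.ascontiguousarray(
            np.asarray(x, dtype=np.float64).transpose(0, 3, 1, 2)))
        return self.conv2(self.conv1(t).relu()).relu()


def _match_channels(m: Tensor, c: int) -> Tensor:
    if m.shape[1] == c:
        return m
    raise ValueError("early-fusion stem width must match the IR branch")
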