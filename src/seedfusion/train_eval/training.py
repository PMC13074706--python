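"""Training loop: AdamW, cosine-annealed learning rate, per-epoch logging.

Reference-scale settings (batch 32, 100 epochs) and desk-scale defaults
(batch 16, 20 epochs) share the same loop; everything is driven by one
seed, so two runs with the same config are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import spawn
from ..model import SeedFusionNet
from ..nn import AdamW, cosine_lr
from ..preprocessing import SeedSample
from .metrics import auc_roc, classification_metrics, confusion_from_predictions

__all__ = ["TrainConfig", "train", "evaluate", "batch_arrays"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16           # reference scale: 32
    epochs: int = 20               # reference scale: 100
    lr_max: float = 1e-4
    lr_min: float = 1e-6
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.lr_min > self.lr_max:
            raise ValueError("lr_min must not exceed lr_max")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


def batch_arrays(samples: list[SeedSample], class_ids: list[str]):
    """Stack a list of samples into model-ready arrays."""
    rgb = np.stack([s.rgb for s in samples])
    ir = np.stack([s.ir for s in samples])
    cls_index = {c: i for i, c in enumerate(class_ids)}
    species = np.array([cls_index[s.class_id] for s in samples])
    via = np.array([0 if s.viability == "viable" else 1 for s in samples])
    return rgb, ir, species, via


def train(model: SeedFusionNet, train_samples: list[SeedSample],
          val_samples: list[SeedSample] | None = None,
          config: TrainConfig | None = None) -> tuple[dict, list[dict]]:
    """Optimise ``model``; returns (best_checkpoint_state, history).

    The best checkpoint is selected by validation total loss (training
    loss when no validation split is given).  A non-finite loss aborts
    with a diagnostic.
    """
    cfg = config or TrainConfig()
    rgb, ir, species, via = batch_arrays(train_samples, model.class_ids)
    n = len(train_samples)
    opt = AdamW(model.parameters(), lr=cfg.lr_max, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    rng = spawn(cfg.seed, "train-shuffle")
    steps_per_epoch = max((n + cfg.batch_size - 1) // cfg.batch_size, 1)
    total_steps = cfg.epochs * steps_per_epoch

    history: list[dict] = []
    best_loss = np.inf
    best_state: dict = model.state_dict()
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.lr = cosine_lr(step, total_steps, cfg.lr_max, cfg.lr_min)
            loss, parts = model.loss(rgb[idx], ir[idx], species[idx], via[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step}: {parts}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.clamp_tau()
            epoch_losses.append(parts)
            step += 1
        record = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean([p["total"] for p in epoch_losses])),
        }
        monitor = record["train_loss"]
        if val_samples:
            val = evaluate(model, val_samples)
            record["val_species_acc"] = val["species_accuracy"]
            record["val_via_acc"] = val["viability_accuracy"]
            record["val_loss"] = val["loss"]
            monitor = val["loss"]
        if monitor < best_loss:
            best_loss = monitor
            best_state = model.state_dict()
        history.append(record)
    return best_state, history


def evaluate(model: SeedFusionNet, samples: list[SeedSample],
             batch_size: int = 64) -> dict:
    """Species/viability metrics (and loss) on a sample list."""
    rgb, ir, species, via = batch_arrays(samples, model.class_ids)
    cls_pred, via_pred, via_scores = [], [], []
    losses = []
    for start in range(0, len(samples), batch_size):
        sl = slice(start, start + batch_size)
        scores, pvia = model.predict(rgb[sl], ir[sl])
        cls_pred.extend(scores.argmax(axis=1))
        via_pred.extend(pvia.argmax(axis=1))
        via_scores.extend(pvia[:, 0])  # score for the "viable" class
        loss, _ = model.loss(rgb[sl], ir[sl], species[sl], via[sl])
        losses.append(loss.item() * len(range(*sl.indices(len(samples)))))
    species_conf = confusion_from_predictions(
        species.tolist(), cls_pred, class_ids=list(range(len(model.class_ids))))
    species_rep = classification_metrics(species_conf)
    via_conf = confusion_from_predictions(via.tolist(), via_pred,
                                          class_ids=[0, 1])
    via_rep = classification_metrics(via_conf)
    out = {
        "species_accuracy": species_rep.accuracy,
        "species_f1": species_rep.f1,
        "viability_accuracy": via_rep.accuracy,
        "viability_f1": via_rep.f1,
        "loss": float(np.sum(losses) / len(samples)),
    }
    viable_truth = (via == 0).astype(int)
    if 0 < viable_truth.sum() < len(viable_truth):
        out["viability_auc"] = auc_roc(via_scores, viable_truth)
    return out
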