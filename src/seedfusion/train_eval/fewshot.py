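"""N-shot evaluation protocol and few-shot adaptation.

For each N in {1, 5, 10, 20}: draw N samples per class with the repeat's
seed, adapt a model on them, evaluate species accuracy on the remainder,
and repeat five times, reporting mean +- sd.  Splits are deterministic
given the spec seed, so paired comparisons between methods share data.

Adaptation freezes the encoders (they are frozen anyway) and trains only
the projection heads, cross-attention and temperature on precomputed
frozen visual features, mirroring the frozen-backbone rationale of the
full model and keeping each episode cheap.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .._rng import spawn
from ..kva import (ProjectionHead, CrossAttention, TinyTextEncoder,
                   TinyVisualEncoder, contrastive_loss, encode_texts)
from ..jlh import ClassPrototypeBank, match_scores, species_loss
from ..nn import AdamW, Parameter, Tensor, l2_normalize, no_grad
from ..preprocessing import SeedSample, Vocabulary

__all__ = ["FewShotSpec", "fewshot_evaluate", "fewshot_splits",
           "KVAFewShotModel", "margin_table"]

DEFAULT_SHOTS = (1, 5, 10, 20)


@dataclass(frozen=True)
class FewShotSpec:
    shots: tuple[int, ...] = DEFAULT_SHOTS
    repeats: int = 5
    seed: int = 0


def fewshot_splits(samples: list[SeedSample], n: int, repeat_seed: int
                   ) -> tuple[list[SeedSample], list[SeedSample]]:
    """N per class into train, remainder into test; errors if impossible."""
    by_class: dict[str, list[SeedSample]] = defaultdict(list)
    for s in samples:
        by_class[s.class_id].append(s)
    rng = spawn(repeat_seed, "fewshot-split")
    train, test = [], []
    for cid in sorted(by_class):
        members = by_class[cid]
        if len(members) <= n:
            raise ValueError(
                f"class {cid} has only {len(members)} samples; needs > {n}")
        order = rng.permutation(len(members))
        train.extend(members[i] for i in order[:n])
        test.extend(members[i] for i in order[n:])
    return train, test


class KVAFewShotModel:
    """Few-shot species classifier: frozen features + metric head.

    Precomputes frozen visual/text features once, then adapts only the
    projection heads, the cross-attention block and the temperature by
    minimising the contrastive + prototype cross-entropy objective on the
    support set.  Prediction is cosine matching of the semantically
    enhanced feature against the class prototype bank.
    """

    def __init__(self, vocab: Vocabulary, corpus: dict[str, list[str]],
                 d: int = 32, dv: int = 32, dt: int = 32, seed: int = 0,
                 steps: int = 60, lr: float = 5e-3):
        self.class_ids = sorted(corpus)
        self.visual_encoder = TinyVisualEncoder(dv, in_channels=3, seed=seed)
        self.text_encoder = TinyTextEncoder(len(vocab), dt, seed=seed)
        self.proj_v = ProjectionHead(dv, d, spawn(seed, "fs-proj-v"))
        self.proj_t = ProjectionHead(dt, d, spawn(seed, "fs-proj-t"))
        self.attn = CrossAttention(d, d, spawn(seed, "fs-attn"))
        self.log_tau = Parameter(np.log(0.07))
        text_feats = encode_texts(corpus, vocab, self.text_encoder)
        self._ft = np.stack([text_feats[c].mean(axis=0)
                             for c in self.class_ids])
        self.steps, self.lr = steps, lr
        self._feat_cache: dict[int, np.ndarray] = {}

    def _features(self, samples: list[SeedSample]) -> np.ndarray:
        out = []
        for s in samples:
            key = id(s)
            if key not in self._feat_cache:
                with no_grad():
                    f = self.visual_encoder(s.rgb[None]).data[0]
                self._feat_cache[key] = f
            out.append(self._feat_cache[key])
        return np.stack(out)

    def _trainables(self):
        return (self.proj_v.parameters() + self.proj_t.parameters()
                + self.attn.parameters() + [self.log_tau])

    def fit(self, support: list[SeedSample]) -> None:
        fv = Tensor(self._features(support))
        labels = np.array([self.class_ids.index(s.class_id) for s in support])
        opt = AdamW(self._trainables(), lr=self.lr, weight_decay=1e-4)
        ft = Tensor(self._ft)
        for _ in range(self.steps):
            tau = self.log_tau.exp()
            zv = self.proj_v(fv)
            prototypes = self.proj_t(ft)
            sem = self.attn(zv, prototypes)
            bank = ClassPrototypeBank(l2_normalize(prototypes), self.class_ids)
            scores = match_scores(sem.fsem, bank)
            loss = (species_loss(scores, labels, Tensor(1.0) / tau)
                    + contrastive_loss(zv, prototypes[labels], tau))
            opt.zero_grad()
            loss.backward()
            opt.step()
            self.log_tau.data = np.clip(self.log_tau.data, np.log(1e-3),
                                        np.log(100.0))

    def predict(self, samples: list[SeedSample]) -> list[str]:
        fv = Tensor(self._features(samples))
        with no_grad():
            zv = self.proj_v(fv)
            prototypes = self.proj_t(Tensor(self._ft))
            sem = self.attn(zv, prototypes)
            bank = ClassPrototypeBank(l2_normalize(prototypes), self.class_ids)
            scores = match_scores(sem.fsem, bank).data
        return [self.class_ids[i] for i in scores.argmax(axis=1)]

    def accuracy(self, samples: list[SeedSample]) -> float:
        preds = self.predict(samples)
        return float(np.mean([p == s.class_id
                              for p, s in zip(preds, samples)]))


def fewshot_evaluate(model_factory, samples: list[SeedSample],
                     spec: FewShotSpec | None = None) -> dict[int, dict]:
    """Run the N-shot protocol; returns {N: {mean, sd, accuracies}}.

    ``model_factory(repeat_seed)`` must return an object with
    ``fit(support)`` and ``accuracy(query)`` methods.
    """
    spec = spec or FewShotSpec()
    results: dict[int, dict] = {}
    for n in spec.shots:
        accs = []
        for rep in range(spec.repeats):
            rep_seed = spawn(spec.seed, "fewshot", n, rep).integers(2**31)
            support, query = fewshot_splits(samples, n, rep_seed)
            model = model_factory(rep_seed)
            model.fit(support)
            accs.append(model.accuracy(query))
        accs = np.asarray(accs)
        results[n] = {"mean": float(accs.mean()),
                      "sd": float(accs.std(ddof=1)),
                      "accuracies": accs.tolist(),
                      "n_train": n * len({s.class_id for s in samples})}
    return results


def margin_table(accuracies: dict[str, float], reference: str) -> dict[str, float]:
    """Accuracy margins of ``reference`` over every other method.

    Operates on printed percentage-scale values and rounds to one decimal,
    matching how benchmark tables report differences.
    """
    if reference not in accuracies:
        raise KeyError(f"reference method {reference!r} missing")
    ref = accuracies[reference]
    return {name: round(ref - value, 1)
            for name, value in accuracies.items() if name != reference}
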