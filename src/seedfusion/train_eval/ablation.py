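"""Paired ablation harness over fusion strategies and components.

Every mode trains from the same data splits, the same seed and the same
schedule, so differences in the comparison table reflect the ablated
pathway, not sampling.  A paired t-test utility over repeated runs is
provided for parity with significance-marked benchmark tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ..model import COMPONENT_MODES, FUSION_MODES, ModelConfig, SeedFusionNet
from ..preprocessing import SeedSample, Vocabulary
from .training import TrainConfig, evaluate, train

__all__ = ["ablation_run", "paired_ttest"]


def ablation_run(train_samples: list[SeedSample],
                 test_samples: list[SeedSample],
                 vocab: Vocabulary, corpus: dict[str, list[str]],
                 modes: list[str],
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None) -> pd.DataFrame:
    """Train/evaluate one model per mode; returns a comparison table.

    ``modes`` may mix fusion strategies (rgb_only, ir_only, early, late,
    ternary) and component ablations (full, no_kva, no_dsf, baseline).
    """
    base = model_config or ModelConfig()
    tcfg = train_config or TrainConfig()
    rows = []
    for mode in modes:
        if mode in FUSION_MODES:
            cfg = base.with_mode(fusion_mode=mode)
        elif mode in COMPONENT_MODES:
            cfg = base.with_mode(component_mode=mode)
        else:
            raise ValueError(f"unknown ablation mode {mode!r}")
        model = SeedFusionNet(cfg, vocab, corpus)
        train(model, train_samples, config=tcfg)
        result = evaluate(model, test_samples)
        rows.append({"mode": mode, **result})
    return pd.DataFrame(rows).set_index("mode")


def paired_ttest(a: list[float], b: list[float]) -> tuple[float, float]:
    """Paired t statistic and p-value over per-repeat accuracies."""
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
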