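"""Shared fixtures.

Heavy artefacts (the desk-scale dataset and the paired ablation runs) are
session-scoped so the stochastic end-to-end suites share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import seedfusion as sf
from seedfusion.preprocessing import Vocabulary
from seedfusion.synthetic import ViabilitySignalSpec, generate_corpus
from seedfusion.train_eval import TrainConfig, ablation_run
from seedfusion.data import stratified_split

SEED = 20240915


@pytest.fixture(scope="session")
def corpus():
    return generate_corpus(6, seed=SEED)


@pytest.fixture(scope="session")
def vocab(corpus):
    return Vocabulary.from_corpus([t for ts in corpus.values() for t in ts])


@pytest.fixture(scope="session")
def small_samples():
    """A small end-to-end dataset (6 per class) for cheap model tests."""
    manifest = sf.desk_manifest(per_class=6, seeds_per_scene=18, seed=SEED)
    return sf.build_dataset(manifest, crop_size=64, seed=SEED)


@pytest.fixture(scope="session")
def desk_dataset():
    """The desk-scale study dataset: 50 seeds/class, IR-only viability signal."""
    manifest = sf.desk_manifest(per_class=50, seeds_per_scene=25, seed=SEED)
    samples = sf.build_dataset(
        manifest, viability_spec=ViabilitySignalSpec(effect_size=0.3),
        crop_size=64, seed=SEED)
    return samples


@pytest.fixture(scope="session")
def desk_splits(desk_dataset):
    return stratified_split(desk_dataset, seed=SEED)


@pytest.fixture(scope="session")
def ablation_results(desk_splits, vocab, corpus):
    """Paired rgb-only / ir-only / ternary training runs (shared seed)."""
    train_s, _, test_s = desk_splits
    return ablation_run(
        train_s, test_s, vocab, corpus,
        ["rgb_only", "ir_only", "ternary"],
        model_config=sf.ModelConfig(seed=SEED),
        train_config=TrainConfig(epochs=20, seed=SEED))
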