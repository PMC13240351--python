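"""Shared fixtures: small synthetic cohorts and a quickly trained model."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import omiclock as oc
from omiclock.train import desk_scale_config


@pytest.fixture(scope="session")
def small_spec() -> oc.SimulationSpec:
    return oc.SimulationSpec(
        n_samples=200,
        n_features={"rna": 60, "methylation": 60},
        n_informative_features={"rna": 8, "methylation": 8},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    dataset, truth = oc.simulate_cohort(small_spec)
    return dataset, truth


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    dataset, _ = small_cohort
    return oc.preprocess_dataset(dataset)


@pytest.fixture(scope="session")
def quick_config() -> oc.ModelConfig:
    return desk_scale_config(seed=7, epochs=6, hidden_sizes=(32,), head_hidden=(32,))


@pytest.fixture(scope="session")
def trained_model(small_preprocessed, quick_config):
    """Pre-trained + fine-tuned model on the small cohort."""
    config = dataclasses.replace(quick_config, epochs=20)
    state, _ = oc.pretrain(small_preprocessed, config)
    finetuned, _ = oc.finetune(
        small_preprocessed, state, dataclasses.replace(config, epochs=30)
    )
    return finetuned


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
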