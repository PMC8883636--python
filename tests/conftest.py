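"""Shared fixtures: deterministic RNGs, small phantoms and a desk-scale
trained model reused by every test that needs a working classifier."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import cloudseg as cs
from cloudseg.synthetic import SynthParams, generate_dataset, make_training_sets

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

SMALL_NET = dict(per_point_layer_sizes=(32, 64, 64), head_layer_sizes=(32,))
SMALL_SCHEDULE = cs.TrainConfig(epochs_stage1=6, epochs_stage2=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def train_samples() -> list:
    return generate_dataset(SynthParams(), 40, 7)


@pytest.fixture(scope="session")
def holdout_samples() -> list:
    return generate_dataset(SynthParams(), 15, 1007)


@pytest.fixture(scope="session")
def small_sets(train_samples):
    return make_training_sets(train_samples, seed=8)


@pytest.fixture(scope="session")
def small_classifier(small_sets):
    """A quickly trained point-set classifier (reduced widths and epochs)."""
    cls_set, _ = small_sets
    model, history = cs.train_classifier(cls_set, SMALL_SCHEDULE, seed=7, **SMALL_NET)
    model.history = history  # stashed for the loss-decrease check
    return model


@pytest.fixture(scope="session")
def small_models(small_classifier, small_sets) -> cs.PipelineModels:
    _, reg_set = small_sets
    regressors = cs.train_regressor(small_classifier, reg_set)
    return cs.PipelineModels(classifier=small_classifier, regressors=regressors)


@pytest.fixture(scope="session")
def small_config() -> cs.PipelineConfig:
    return cs.PipelineConfig(
        train=SMALL_SCHEDULE,
        n_train=40,
        seed=7,
        **SMALL_NET,
    )


def random_mask_pair(rng: np.random.Generator, shape=(32, 32), p=0.3):
    T = cs.SegMask((rng.random(shape) < p).astype(np.uint8))
    G = cs.SegMask((rng.random(shape) < p).astype(np.uint8))
    return T, G
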