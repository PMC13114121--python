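"""Shared fixtures: all data is generated in-process from fixed seeds."""

from __future__ import annotations

import numpy as np
import pytest

import priorvae as pv


@pytest.fixture(scope="session")
def tiny_prior() -> pv.PriorMatrix:
    rng = np.random.default_rng(7)
    return pv.PriorMatrix([f"p{i}" for i in range(5)], rng.standard_normal((5, 12)))


@pytest.fixture(scope="session")
def tiny_config() -> pv.NetworkConfig:
    return pv.NetworkConfig(
        input_dim=9, latent_dim=8, hidden_dim=10, prior_dim=12, n_heads=2,
        classifier_dims=(6, 4), seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort() -> pv.Cohort:
    """A small separable cohort for fast end-to-end runs."""
    spec = pv.SyntheticSpec(
        n_samples=100, n_features=60, n_informative=15, effect_size=2.0,
        zero_inflation=0.6, seed=11,
    )
    return pv.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_prior() -> pv.PriorMatrix:
    return pv.generate_prior(pv.SyntheticSpec(n_prior=16, seed=11))


@pytest.fixture(scope="session")
def small_cv(small_cohort, small_prior) -> pv.EvalResult:
    """Five-fold CV on the small cohort; reused by several test modules."""
    cfg = pv.NetworkConfig(input_dim=60, latent_dim=32, hidden_dim=48, n_heads=4,
                           prior_dim=320, classifier_dims=(16, 8), seed=42)
    settings = pv.TrainSettings(epochs=30, seed=42)
    return pv.run_cv(
        small_cohort.abundance, small_cohort.labels, small_prior, cfg, settings,
        select_k=20,
    )
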