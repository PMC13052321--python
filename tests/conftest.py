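"""Shared fixtures.

The expensive artifacts (simulated study datasets, trained generators) are
built once per session and shared; generator training for the end-to-end
checks is cached per seed so the adversarial-training tests and the
augmentation tests reuse the same runs.
"""

from __future__ import annotations

from functools import lru_cache

import pytest
from hypothesis import HealthCheck, settings

from pkgan import FeatureScaler, WGANGP, simulate_dataset, to_feature_table
from pkgan.popsim import censor_blq

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: epochs used for the scaled-down end-to-end generator trainings
TRAIN_EPOCHS = 20_000


@pytest.fixture(scope="session")
def study():
    """One seeded original study: covariates, observations, long dataset."""
    cov, obs, long_df = simulate_dataset(seed=1)
    return {"cov": cov, "obs": obs, "long": long_df}


@pytest.fixture(scope="session")
def feature_setup(study):
    """Feature table, fitted scaler and scaled table for the seeded study."""
    table = to_feature_table(
        study["cov"], censor_blq(study["obs"], 0.5, "flag"), dose=300.0
    )
    scaler = FeatureScaler().fit(table)
    return {"table": table, "scaler": scaler, "scaled": scaler.transform(table)}


@lru_cache(maxsize=8)
def pipeline_run(seed: int):
    """Simulate -> encode -> train (scaled-down) for one pipeline seed.

    Cached so every test interrogating the same seed shares one training.
    """
    cov, obs, long_df = simulate_dataset(seed=seed)
    table = to_feature_table(cov, censor_blq(obs, 0.5, "flag"), dose=300.0)
    scaler = FeatureScaler().fit(table)
    scaled = scaler.transform(table)
    gan = WGANGP(epochs=TRAIN_EPOCHS, random_state=seed).fit(scaled, scaler=scaler)
    return {
        "cov": cov,
        "obs": obs,
        "long": long_df,
        "table": table,
        "scaler": scaler,
        "scaled": scaled,
        "gan": gan,
    }
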