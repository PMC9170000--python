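"""Shared fixtures: a reduced-scale synthetic campaign and one MCMC fit.

The campaign keeps the full hierarchical structure (3 jobs, per-day
intercepts and variances, spline trends, events) at a size where a
Gibbs fit takes seconds: 6 monitored days, 8 station categories,
4 environments, 3 event types, 2-minute mass records.
"""

import numpy as np
import pytest

from pmspline.model import ModelSpec, build_model, fit
from pmspline.simulate import SimConfig, generate_dataset
from tests_helpers import build_from_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        seed=11, n_jobs=3, days_per_job=2, n_stations=8, n_environments=4,
        n_events=3, shift_minutes=360, mass_dt=120, number_dt=30,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_design(small_dataset):
    return build_from_dataset(small_dataset)


@pytest.fixture(scope="session")
def small_spec() -> ModelSpec:
    return ModelSpec(chains=3, iterations=1500, burn_in=500, seed=2)


@pytest.fixture(scope="session")
def small_fit(small_design, small_spec):
    model = build_model(small_design, small_spec)
    draws = fit(model)
    return model, draws


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
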