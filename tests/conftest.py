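"""Shared fixtures.

The two expensive end-to-end runs (the 50k-point recovery scenario and the
scaled-down bootstrap study) are session-scoped and shared between the unit
and acceptance tests so each runs exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import refcurve as rc

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from refcurve.pipeline import fit_pipeline
from refcurve.synthetic_data import alp_like, generate_dataset


@pytest.fixture(scope="session")
def alp_scenario():
    """The recovery scenario: ALP-like truth curves, n = 50k, 10%
    one-sided pathological contamination, one sample per subject."""
    return alp_like(n_total=50_000, seed=20260901, pathological_fraction=0.10,
                    samples_per_subject=((1, 1.0),))


@pytest.fixture(scope="session")
def alp_dataset(alp_scenario):
    return generate_dataset(alp_scenario)


@pytest.fixture(scope="session")
def alp_run(alp_scenario, alp_dataset):
    """Full pipeline run (partition, indirect fits, weighting, GAMLSS with
    family selection) on the recovery scenario."""
    ms, _ = alp_dataset
    config = rc.PipelineConfig(rng_seed=11)
    grid = np.linspace(ms.age_days.min(), ms.age_days.max(), 50).astype(int)
    return fit_pipeline(ms, config, age_grid=grid)


@pytest.fixture(scope="session")
def bootstrap_run(bootstrap_inputs):
    """Scaled-down bootstrap study: B = 20 replicate pipeline runs on a
    10k-point dataset."""
    ms, config, point = bootstrap_inputs
    boot = rc.bootstrap_percentile_ci(ms, config, point.percentile_table,
                                      point_model=point.model)
    return boot


@pytest.fixture(scope="session")
def bootstrap_inputs():
    sc = alp_like(n_total=10_000, seed=4711, pathological_fraction=0.10)
    ms, _ = generate_dataset(sc)
    config = rc.PipelineConfig(rng_seed=5, bootstrap_B=20, families=("BCCG",))
    # cap the grid at the 99th age percentile so every bootstrap resample
    # still covers it (the single oldest rows are missed by ~37% of draws)
    hi = int(np.quantile(ms.age_days, 0.99))
    ages = np.linspace(0, hi, 25).astype(int)
    point = fit_pipeline(ms, config, age_grid=ages)
    return ms, config, point
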