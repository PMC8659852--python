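"""Shared fixtures: noiseless generator settings and small cohorts."""

from __future__ import annotations

import pytest

from aptascreen.features import build_feature_table, extract_sample_record
from aptascreen.synthetic import (CohortConfig, CVShapeParams, HDrift,
                                  NoiseConfig, default_cv_shape,
                                  simulate_cohort)


@pytest.fixture
def noiseless_shape() -> CVShapeParams:
    return default_cv_shape(noise_sd=0.0)


@pytest.fixture
def flat_noiseless_shape() -> CVShapeParams:
    """Zero baseline, zero noise: the trace is the bare peak function."""
    return default_cv_shape(noise_sd=0.0, baseline_slope=0.0,
                            baseline_offset=0.0)


@pytest.fixture(scope="session")
def quiet_cohort_records():
    """Zero-noise, zero-drift 3+3 cohort (deterministic round-trip data)."""
    config = CohortConfig(
        n_lc=3, n_h=3, seed=11,
        noise=NoiseConfig(cv_noise_sd=0.0, eis_noise_fraction=0.0),
        h_drift=HDrift(potential_V=0.0, current_frac=0.0, cpe_frac=0.0),
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort_table():
    """The default study conditions: 10 LC + 10 H, seed 1, full base set."""
    records = simulate_cohort(CohortConfig(n_lc=10, n_h=10, seed=1))
    feature_records = [
        extract_sample_record(
            r.sample_id, r.label,
            cv_before=r.before.cv, eis_before=r.before.eis,
            cv_after=r.after.cv, eis_after=r.after.eis,
        )
        for r in records
    ]
    return build_feature_table(feature_records, "full")
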