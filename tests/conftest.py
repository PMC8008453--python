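"""Shared fixtures: published-parameter models and calibrated synthetic data."""
from __future__ import annotations

import numpy as np
import pytest

import mehgsim as m
from mehgsim.synthetic import (
    CONSUMER_PROPORTIONS,
    OBSERVED_GROUP_MAXIMA,
)


@pytest.fixture(scope="session")
def tuna_params() -> m.LogNormalParams:
    """Log-normal model for the highest-concentration group (mean 0.54, SD 0.53)."""
    return m.moments_to_logparams(0.54, 0.53)


@pytest.fixture(scope="session")
def published_params() -> dict[m.FishGroup, m.LogNormalParams]:
    return m.published_concentration_params()


@pytest.fixture(scope="session")
def group_caps() -> dict[m.FishGroup, float]:
    return dict(OBSERVED_GROUP_MAXIMA)


@pytest.fixture(scope="session")
def calibrated_survey() -> dict[m.FishGroup, m.ConsumptionRecords]:
    """One full-size synthetic survey calibrated to the published summaries."""
    return m.generate_survey(m.default_survey_spec(seed=2021))


@pytest.fixture(scope="session")
def conc_datasets() -> dict[m.FishGroup, m.ConcentrationDataset]:
    """Synthetic concentration datasets (210 samples, capped at group maxima)."""
    return m.generate_concentration_datasets(seed=77)


@pytest.fixture(scope="session")
def exact_proportion_records() -> dict[m.FishGroup, m.ConsumptionRecords]:
    """Records whose consumer fractions equal the published proportions exactly.

    Each group holds 1000 person-days with exactly 1000*p positive amounts
    (the published proportions are all integer at that size), so resampling is
    zero with probability exactly 1 - p.
    """
    rng = np.random.default_rng(424242)
    records = {}
    for group, p in CONSUMER_PROPORTIONS.items():
        n = 1000
        k = round(p * n)
        assert abs(k - p * n) < 1e-9  # proportions are exact at n=1000
        amounts = np.zeros(n)
        amounts[:k] = rng.lognormal(mean=3.0, sigma=1.0, size=k)  # skewed g/day
        records[group] = m.ConsumptionRecords(group, amounts)
    return records
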