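"""Shared fixtures: simulated cohorts are expensive, so build them once."""

from __future__ import annotations

import numpy as np
import pytest

from citnirs.pipeline import simulate_features
from citnirs.synthetic import CohortSpec, EffectSpec


@pytest.fixture(scope="session")
def default_cohort():
    """Default 30 CL + 25 HC cohort with the planted delta = 0.5 effect."""
    return simulate_features(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def default_table(default_cohort):
    return default_cohort[1]


@pytest.fixture(scope="session")
def null_table():
    """Same cohort conditions but no group effect (delta = 0)."""
    _, table = simulate_features(CohortSpec(seed=11), effect=EffectSpec(delta=0.0))
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
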