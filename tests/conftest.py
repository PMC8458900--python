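"""Shared fixtures: the default basal set and small reusable cohorts."""

import numpy as np
import pytest

from hpa_pipeline import (
    NetworkSpec,
    ParameterSet,
    PulseProtocol,
    SimConfig,
    sample_population,
)
from hpa_pipeline.config import default_basal
from hpa_pipeline.protocols import run_cohort


@pytest.fixture(scope="session")
def basal() -> ParameterSet:
    params, _ = default_basal()
    return params


@pytest.fixture(scope="session")
def spec() -> NetworkSpec:
    return NetworkSpec()


@pytest.fixture(scope="session")
def pulse() -> PulseProtocol:
    return PulseProtocol()


@pytest.fixture(scope="session")
def sim() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def small_cohort(basal, pulse, sim):
    """2,000 stressed individuals; yields all three phenotype classes."""
    pop = sample_population(basal, fold=10.0, n=2000, seed=1234)
    return run_cohort(pop, pulse, sim)


@pytest.fixture(scope="session")
def low_patients(small_cohort):
    return [p for p in small_cohort if p.phenotype.label == "low_cortisol"]


@pytest.fixture(scope="session")
def high_patients(small_cohort):
    return [p for p in small_cohort if p.phenotype.label == "high_cortisol"]


def random_parameter_set(rng: np.random.Generator,
                         basal: ParameterSet) -> ParameterSet:
    """One individual drawn with the 10-fold uniform scheme (test helper)."""
    base = basal.as_array()
    mags = rng.uniform(np.abs(base) / 10.0, np.abs(base) * 10.0)
    return ParameterSet.from_array(np.sign(base) * mags)
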