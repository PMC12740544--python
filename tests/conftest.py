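import logging

import numpy as np
import pytest

from dosim.kinetics import DEFAULT_CONSTANTS, SOEFParameters
from dosim.nlmem import FitConfig, PopulationModel, fit_population, initial_model_heuristic
from dosim.simulate import SimulationConfig, generate_cohort

logging.getLogger("dosim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def consts():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def example_params():
    """A plausible kidney parameter set used throughout the suite."""
    return SOEFParameters(
        A1=0.02, A2=0.01, A3=0.025, lambda1=0.005, lambda2=0.05, lambda3=2.0
    )


@pytest.fixture(scope="session")
def default_truth_model():
    return PopulationModel(
        theta=np.array([0.02, 0.01, 0.025, 0.005, 0.05, 2.0]),
        omega=np.full(6, 0.09),
        sigma=0.10,
    )


def random_valid_params(rng):
    """Random positive SOEF parameters spanning the physiological decades."""
    a = rng.uniform(0.3, 3.0, 3) * np.array([0.02, 0.01, 0.025])
    lam = np.array([0.005, 0.05, 2.0]) * rng.uniform(0.3, 3.0, 3)
    return SOEFParameters(a[0], a[1], a[2], lam[0], lam[1], lam[2])


@pytest.fixture(scope="session")
def small_cohort():
    """Ten virtual subjects at the five nominal sessions (seeded)."""
    cfg = SimulationConfig(n_subjects=10, seed=42)
    dataset, truths = generate_cohort(cfg)
    return dataset, truths, cfg


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Population fit on the ten-subject cohort, shared across tests."""
    dataset, _, _ = small_cohort
    init = initial_model_heuristic(dataset)
    config = FitConfig(n_starts=2, seed=0, compute_cov=False)
    return fit_population(dataset, init, config)
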