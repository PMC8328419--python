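import numpy as np
import pandas as pd
import pytest

from deepfd.synthetic import (
    SimulationParams, StudyDesign, simulate_measurements, simulate_traits,
)


@pytest.fixture(scope="session")
def small_community():
    """A small but fully structured synthetic community (traits only)."""
    params = SimulationParams(
        n_species=15, mean_occ_richness=6, measured_fraction=0.5, seed=11
    )
    return simulate_traits(StudyDesign(), params)


@pytest.fixture(scope="session")
def small_morpho(small_community):
    """Raw measurement layer of the small community."""
    return simulate_measurements(small_community.individuals, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
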