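import numpy as np
import pytest

from dentimp import (
    DEFAULT_GRID,
    FrequencyGrid,
    reconstruct_reference,
    reference_emulated_model,
    emulated_impedance,
)


@pytest.fixture(scope="session")
def study_grid() -> FrequencyGrid:
    """The 1400-point log grid from 10 mHz to 10 MHz."""
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def coarse_grid() -> FrequencyGrid:
    """A cheaper grid spanning the same band, for fitting tests."""
    return FrequencyGrid(10e-3, 10e6, 250)


@pytest.fixture(scope="session")
def young_spectrum(study_grid):
    return reconstruct_reference("young", study_grid)


@pytest.fixture(scope="session")
def old_spectrum(study_grid):
    return reconstruct_reference("old", study_grid)


@pytest.fixture(scope="session")
def young_emulated(study_grid):
    return emulated_impedance(reference_emulated_model("young"), study_grid)


@pytest.fixture(scope="session")
def old_emulated(study_grid):
    return emulated_impedance(reference_emulated_model("old"), study_grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
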