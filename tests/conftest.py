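import numpy as np
import pytest

from riskbn import (
    apply_transforms,
    build_fractional_design,
    default_ground_truth,
    simulate_indicator_table,
)


@pytest.fixture(scope="session")
def design():
    return build_fractional_design()


@pytest.fixture(scope="session")
def dynamics_gt():
    return default_ground_truth("dynamics")


@pytest.fixture(scope="session")
def maxima_gt():
    return default_ground_truth("maxima")


@pytest.fixture(scope="session")
def fullscale_table(design, dynamics_gt):
    """27 participants x 32 factorial trials (+4 collisions each), raw scale."""
    return simulate_indicator_table(design, 27, dynamics_gt, seed=20240917)


@pytest.fixture(scope="session")
def fullscale_transformed(fullscale_table):
    return apply_transforms(fullscale_table)


@pytest.fixture(scope="session")
def small_transformed(design, dynamics_gt):
    """A cheap 8-participant table for search-level tests."""
    table = simulate_indicator_table(design, 8, dynamics_gt, seed=77)
    return apply_transforms(table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
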