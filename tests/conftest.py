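import numpy as np
import pytest

from hscdiv.division_fractions import DivisionThresholds
from hscdiv.synthetic_data import (
    DEFAULT_ODE_PARAMS,
    DEFAULT_THRESHOLDS,
    DEFAULT_TRAJECTORY,
    generate_census,
    generate_wells,
    paper_like_spec,
)


@pytest.fixture(scope="session")
def truth_traj():
    return DEFAULT_TRAJECTORY


@pytest.fixture(scope="session")
def truth_thr() -> DivisionThresholds:
    return DEFAULT_THRESHOLDS


@pytest.fixture(scope="session")
def truth_params():
    return DEFAULT_ODE_PARAMS


@pytest.fixture(scope="session")
def wells_table():
    """One synthetic ex vivo study at the default design (seed 7)."""
    return generate_wells(paper_like_spec(seed=7))


@pytest.fixture(scope="session")
def census_noisefree():
    """Census lying exactly on the truth model curves."""
    return generate_census(paper_like_spec(seed=7, census_sigma=0.0))


@pytest.fixture(scope="session")
def census_noisy():
    return generate_census(paper_like_spec(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240129)
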