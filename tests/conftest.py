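import warnings

import pytest

import ssf_assess as sa


@pytest.fixture(scope="session")
def small_survey():
    """A small simulated survey shared across read-only tests."""
    survey, truth = sa.simulate_survey(sa.SimConfig(n_fishers=30, seed=11))
    return survey, truth


@pytest.fixture(scope="session")
def small_frames(small_survey):
    survey, truth = small_survey
    return sa.periods_frame(survey), sa.species_frame(survey), truth


@pytest.fixture(scope="session")
def worked_example():
    return sa.load_worked_example()


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Boundary REML fits warn; the tests assert on the numbers instead."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
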