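import pytest

from chronobayes.distributions import duration_grid, make_candidate_prior
from chronobayes.observer import LossSpec, NoiseModel, ObserverModel
from chronobayes.synthetic import BlockDesign, simulate_trials


@pytest.fixture(scope="session")
def grid5():
    """Coarse 5-ms duration grid used by the heavier quadrature tests."""
    return duration_grid(step=5.0)


@pytest.fixture(scope="session")
def medium_design():
    return BlockDesign("medium_uniform", feedback="standard")


@pytest.fixture(scope="session")
def gaussian_observer(medium_design, grid5):
    """Scalar/scalar observer with the moment-matched Gaussian prior."""
    prior = make_candidate_prior("b", "medium_uniform", grid5)
    return ObserverModel(NoiseModel("scalar", 0.1), NoiseModel("scalar", 0.1),
                         prior, LossSpec("standard"),
                         lapse_range=medium_design.allowed_window)


@pytest.fixture(scope="session")
def medium_trials(medium_design, gaussian_observer):
    """A session-shared synthetic subject: 600 Medium Uniform trials."""
    return simulate_trials(medium_design, gaussian_observer,
                           n_trials=600, seed=11, grid=duration_grid(step=5.0))
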