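import warnings

import numpy as np
import pytest

# VL emits a RuntimeWarning when stopped at max_iter; tests that care
# about convergence assert on the posterior, not the warning
warnings.filterwarnings(
    "ignore", message="variational_laplace", category=RuntimeWarning
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def fast_stimulus():
    """Two-cycle stimulus at the fitting resolution."""
    from pursuitdcm.stimulus import StimulusConfig

    return StimulusConfig(cycles_per_trial=2, dt=0.005)


@pytest.fixture(scope="session")
def default_params():
    from pursuitdcm.agent import PursuitParams

    return PursuitParams()


@pytest.fixture(scope="session")
def smooth_sim(fast_stimulus, default_params):
    """One deterministic smooth-condition simulation, shared."""
    from pursuitdcm.inference_loop import simulate_pursuit

    return simulate_pursuit(fast_stimulus, default_params, "smooth",
                            seed=0, dt=0.005)
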