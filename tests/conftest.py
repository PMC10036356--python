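import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def ref():
    from mucorheo.sample_qc import TonicityReference

    return TonicityReference()


@pytest.fixture(scope="session")
def newtonian_water_like():
    """alpha = 1, eta = 1 mPa s: D = k_B T / (6 pi eta a) = 0.4368 um^2/s."""
    from mucorheo.synthetic_data import FluidModel

    return FluidModel(alpha=1.0, eta_1hz=1e-3)


@pytest.fixture(scope="session")
def critical_gel():
    """tan delta = tan(pi alpha / 2) = 0.300 at alpha = 0.1856."""
    from mucorheo.synthetic_data import FluidModel

    return FluidModel(alpha=0.1856, eta_1hz=0.05)


@pytest.fixture(scope="session")
def gel_tracks(critical_gel):
    """100 simulated beads in the critical gel, with localization noise."""
    from mucorheo.synthetic_data import TrajectoryParams, simulate_fbm_tracks

    params = TrajectoryParams(n_beads=100, n_frames=600, localization_sigma_um=0.02)
    return simulate_fbm_tracks(critical_gel, params, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)
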