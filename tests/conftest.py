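import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def linearized_movie():
    """Pure linearized contraction, no diffusion, experimental-like SNR."""
    from frapgrid import simulate_grid_movie
    return simulate_grid_movie(alpha=2e-3, d=0.0,
                               mode="linearized_lagrangian", seed=3,
                               n_filaments=400_000)


@pytest.fixture(scope="session")
def ou_movie():
    """Ornstein-Uhlenbeck dynamics with contraction and diffusion."""
    from frapgrid import simulate_grid_movie
    return simulate_grid_movie(alpha=2e-3, d=1e-3, mode="eulerian_ou",
                               seed=5, n_filaments=200_000)


@pytest.fixture(scope="session")
def static_movie():
    """No dynamics, no camera noise: frames are identical."""
    from frapgrid import simulate_grid_movie
    return simulate_grid_movie(alpha=0.0, d=0.0, mode="eulerian_ou",
                               seed=7, n_filaments=400_000, noise=False)
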