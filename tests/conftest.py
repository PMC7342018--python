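import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def linear_track():
    """Noiseless constant-velocity track: v = 0.5 um/min apical, 21 points."""
    from iknm import NuclearTrack

    times = np.arange(21.0) - 20.0
    positions = -0.5 * times  # 10 um at t = -20, 0 at metaphase
    return NuclearTrack(track_id="lin", times=times, positions=positions)


@pytest.fixture(scope="session")
def brownian_cohort():
    """200 pure-Brownian tracks, D = 0.05 um^2/min, N = 100, dt = 1 min."""
    from iknm import SimConfig, simulate_tracks

    cfg = SimConfig(
        seed=11, dt=1.0, n_steps=99, d_early=0.05, confinement_k=0.0,
        v_late=0.0, d_late=0.05, t_onset=0.0, p0=25.0, meas_noise_sd=0.0,
        n_tracks=200,
    )
    return simulate_tracks(cfg)


@pytest.fixture(scope="session")
def drift_cohort():
    """100 two-phase tracks: diffusive early, 0.6 um/min drift from -15 min."""
    from iknm import SimConfig, simulate_tracks

    cfg = SimConfig(
        seed=21, dt=1.0, n_steps=60, d_early=0.1, confinement_k=0.0,
        v_late=0.6, d_late=0.05, t_onset=-15.0, p0=20.0, meas_noise_sd=0.0,
        n_tracks=100,
    )
    return simulate_tracks(cfg)
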