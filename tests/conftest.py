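import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tugait.pipeline import PipelineConfig, run_session
from tugait.simulate import living_room, simulate_trial

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Subject statures (m) used for sampled-height simulations.
SUBJECT_HEIGHTS = [1.76, 1.78, 1.82, 1.68, 1.61, 1.85, 1.74, 1.71, 1.80, 1.78]


@pytest.fixture(scope="session")
def clean_living_trial():
    """One noise-free living-room trial (far 4.6 m, near 1.6 m, cam 0.9 m)."""
    cfg = living_room(
        subject_height_m=1.76, pixel_noise_sigma_px=0.0, pose_noise_m=0.0, seed=7
    )
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def clean_living_report(clean_living_trial):
    config = PipelineConfig(subject_height_m=1.76, cam_height_m=0.9)
    return run_session(clean_living_trial.kp2d, clean_living_trial.kp3d, config)
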