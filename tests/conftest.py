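import numpy as np
import pytest

from fundusburst import BurstConfig, generate_phantom, simulate_burst
from fundusburst.synthetic import IlluminationSchedule

SIDE = 160


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(seed=1, side_px=SIDE)


@pytest.fixture(scope="session")
def still_illumination():
    """Vignette with no frame-to-frame jitter: frames differ only through
    gaze, artifacts and noise."""
    return IlluminationSchedule(vignette_strength=0.25, center_jitter_px=0.0)


@pytest.fixture(scope="session")
def clean_stack(phantom, still_illumination):
    """Noise-free, artifact-free, gaze-free burst: all frames identical."""
    cfg = BurstConfig(n_frames=4, gaze_model=[(0, 0)] * 4, noise_sd=0.0,
                      illumination=still_illumination, seed=3)
    return simulate_burst(phantom, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
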