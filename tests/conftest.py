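import numpy as np
import pytest

from pulsecam import SceneParams
from pulsecam.video_io import Rect


@pytest.fixture
def default_params() -> SceneParams:
    return SceneParams(seed=42)


@pytest.fixture
def quiet_params() -> SceneParams:
    """Noise- and drift-free scene: the modulations alone."""
    return SceneParams(noise_sd=0.0, drift_amp=0.0, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def face_and_body() -> tuple[Rect, Rect]:
    return Rect(100, 100, 100, 120), Rect(50, 80, 200, 300)
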