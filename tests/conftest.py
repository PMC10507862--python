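import numpy as np
import pytest

from bilgmd import CameraRig, ChannelParams


@pytest.fixture
def params():
    """Default cascade parameters (n_p=1, W_I=0.3, C_w=4, Δc=0.01, T_de=30)."""
    return ChannelParams()


@pytest.fixture
def tiny_rig():
    """Rig from the worked projection example: b*f/pixelsize = 200 m*px."""
    return CameraRig(
        baseline_m=0.1, focal_m=0.004, pixel_size_m=2e-6, rows=64, cols=64
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230905)
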