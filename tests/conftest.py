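import numpy as np
import pytest

from ccpquant import detection, synthgen


@pytest.fixture
def det_cfg():
    return detection.DetectionConfig()


@pytest.fixture
def snr10_still():
    """One 256x256 frame with 50 well-separated spots at SNR ~10."""
    spec = synthgen.MovieSpec(
        width=256, height=256, n_frames=1, nucleation_rate=0.0,
        persistent_count=50, spot_amplitude_range=(108.0, 108.01), seed=3)
    stacks, gt = synthgen.generate_movie(spec)
    return stacks["master"].data[0], gt, spec


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
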