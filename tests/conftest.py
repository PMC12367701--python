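import numpy as np
import pytest

from mstf.core import ChannelInfo, EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def channels():
    """Six scalp channels plus one EOG channel."""
    labels = ["Fz", "Cz", "Pz", "Oz", "C3", "C4", "VEOG"]
    return ChannelInfo(labels)


@pytest.fixture
def random_epochs(rng, channels):
    """Small finite epoch set: 3 epochs x 7 channels x 50 samples at 1 kHz."""
    data = rng.normal(0, 5, (3, channels.n_channels, 50))
    return EpochSet(data, 1000.0, -20.0, channels, condition="test")
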