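import sys
from pathlib import Path

import numpy as np
import pytest

# make the brute-force oracles importable as plain modules
sys.path.insert(0, str(Path(__file__).parent))

from frcmech.core import CalibratedImage2D


@pytest.fixture
def flat_image():
    return CalibratedImage2D(np.zeros((32, 32)), pixel_size_um=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
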