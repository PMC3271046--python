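import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bronchosum import DctDetectorModel, make_informative_frame


@pytest.fixture(scope="session")
def default_model() -> DctDetectorModel:
    return DctDetectorModel()


@pytest.fixture(scope="session")
def sharp_frames():
    """Twenty seeded sharp fixture frames (mixed lumen counts)."""
    return [
        make_informative_frame(seed=100 + i, size=128, n_lumina=1 + i % 3)[0]
        for i in range(20)
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
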