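import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from eeglgs import EEGRecording  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noise_recording(rng):
    """19-channel white-noise recording, 166,000 samples at 500 Hz."""
    return EEGRecording(
        data=rng.standard_normal((19, 166_000)),
        fs=500.0,
        subject_id="noise",
    )


@pytest.fixture
def small_recording(rng):
    """4-channel recording long enough for one 2,000-sample segment."""
    return EEGRecording(
        data=rng.standard_normal((4, 2_000)), fs=500.0, subject_id="small"
    )
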