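import numpy as np
import pytest

from drowsyhrv.hrv_series import HRVSeries
from drowsyhrv.ppg_preprocess import IBISeries
from drowsyhrv.synthetic_data import GroundTruth


def hrv_from_array(values, fs_hz=7.0, start_s=0.0) -> HRVSeries:
    return HRVSeries(values=np.asarray(values, dtype=float),
                     fs_hz=fs_hz, start_s=start_s)


def sinusoid_window(n=420, fs=7.0, mean=1.0, components=((0.05, 0.1),)) -> HRVSeries:
    """HRV window = mean + sum of (amp, freq) sinusoids on the grid."""
    t = np.arange(n) / fs
    x = np.full(n, float(mean))
    for amp, freq in components:
        x = x + amp * np.sin(2 * np.pi * freq * t)
    return hrv_from_array(x, fs)


def ibi_from_ground_truth(gt: GroundTruth, fs=40.0) -> IBISeries:
    """Wrap ground-truth beats as a validated interval series."""
    return IBISeries(beat_times_s=gt.beat_times_s, intervals_s=gt.ibi_s,
                     knot_times_s=gt.beat_times_s[1:], source_fs_hz=fs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stationary_window():
    """1-min HRV window with LF and HF sinusoids of equal amplitude."""
    return sinusoid_window(components=((0.05, 0.1), (0.05, 0.3)))
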