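"""Raw PPG to beat sequence: differencing, peak detection, P-P intervals.

Motion of the hand on the steering wheel shows up in a finger PPG as
baseline steps and drifts.  A first-order difference,
``v[x] = (y[x] - y[x-1]) / dt``, maps a constant offset to zero and a
linear drift to a constant, so beat detection on the differenced signal is
insensitive to these artifacts while the steep systolic upstroke of each
pulse survives as a prominent positive lobe.

Beat detection is deliberately parameter-light: smooth the differenced
signal with a 0.1 s moving average, threshold at half the rolling 75th
percentile of its positive part (5 s window), enforce a 0.3 s refractory
period (caps heart rate at 200 bpm), then refine each detection to the
nearest raw-waveform local maximum within ±0.15 s so reported beat times
sit on the pulse peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "PPGRecord",
    "DiffSeries",
    "IBISeries",
    "differentiate",
    "detect_peaks",
    "to_ibi",
    "preprocess",
]

#: physiologically plausible P-P interval range, seconds (exclusive bounds)
IBI_MIN_S = 0.3
IBI_MAX_S = 2.0
#: relative change vs the previous valid interval beyond which an
#: interval is treated as ectopic/missed-beat and excluded
MAX_RELATIVE_STEP = 0.75

SMOOTH_S = 0.1
BASELINE_S = 0.35
THRESHOLD_WINDOW_S = 5.0
THRESHOLD_QUANTILE = 0.75
THRESHOLD_SCALE = 0.5
THRESHOLD_FLOOR = 0.25
HEIGHT_OUTLIER_FACTOR = 4.0
DOWNSTROKE_S = 0.35
DOWNSTROKE_FRACTION = 0.15
REFRACTORY_S = 0.3
REFINE_S = 0.15


@dataclass(frozen=True)
class PPGRecord:
    """Uniformly sampled PPG waveform."""

    samples: np.ndarray
    fs_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def duration_s(self) -> float:
        return (self.samples.size - 1) / self.fs_hz if self.samples.size else 0.0


@dataclass(frozen=True)
class DiffSeries:
    """First-order difference of a PPG record (amplitude per second)."""

    values: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class IBISeries:
    """Validated peak-to-peak intervals.

    ``intervals_s[i]`` is anchored at ``knot_times_s[i]``, the time of the
    second beat of its pair — the moment the interval becomes known.
    Intervals rejected by the validity filter leave a gap in the knots;
    ``beat_times_s`` retains every accepted beat.
    """

    beat_times_s: np.ndarray
    intervals_s: np.ndarray
    knot_times_s: np.ndarray
    source_fs_hz: float

    def __post_init__(self) -> None:
        for name in ("beat_times_s", "intervals_s", "knot_times_s"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if self.beat_times_s.size and np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat_times_s must be strictly increasing")
        if self.intervals_s.size != self.knot_times_s.size:
            raise ValueError("one knot time per interval required")


def differentiate(rec: PPGRecord) -> DiffSeries:
    """First-order difference, ``v[x] = (y[x] - y[x-1]) * fs``.

    Output has one sample fewer than the input.  Linear in the input;
    constant offsets map to zero and linear drifts to a constant.
    """
    y = rec.samples
    if y.size < 2:
        raise ValueError("signal too short: need at least 2 samples")
    return DiffSeries(values=np.diff(y) * rec.fs_hz, fs_hz=rec.fs_hz)


def _rolling_positive_quantile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Centered rolling quantile over the positive samples of ``x``."""
    s = pd.Series(np.where(x > 0, x, np.nan))
    out = s.rolling(window, center=True, min_periods=1).quantile(q).to_numpy()
    return np.nan_to_num(out, nan=0.0)


def detect_peaks(rec: PPGRecord, domain: str = "diff") -> np.ndarray:
    """Detect beat sample indices in a PPG record.

    With ``domain="diff"`` (default) the detector runs on the smoothed
    first difference — robust to baseline steps and drifts — and each
    detection is then refined to the nearest raw local maximum within
    ±0.15 s.  ``domain="raw"`` searches the raw waveform directly.

    Returns a strictly increasing index array; an empty array (with a
    warning) when no plausible beats are found.
    """
    fs = rec.fs_hz
    if rec.duration_s < 2.0:
        raise ValueError("signal duration must be at least 2 s")
    if domain not in ("diff", "raw"):
        raise ValueError("domain must be 'diff' or 'raw'")

    if domain == "diff":
        v = differentiate(rec).values
        k = max(int(round(SMOOTH_S * fs)), 1)
        smooth = np.convolve(v, np.ones(k) / k, mode="same")
    else:
        smooth = rec.samples.copy()

    # a linear raw-signal drift becomes a constant offset after differencing
    # and slower motion artifacts become second-scale bumps; a short
    # moving-average baseline removes both while the ~0.1 s systolic
    # upstroke passes nearly untouched
    kb = max(int(round(BASELINE_S * fs)), 1)
    baseline = (pd.Series(smooth)
                .rolling(kb, center=True, min_periods=1).mean().to_numpy())
    win = max(int(round(THRESHOLD_WINDOW_S * fs)), 1)
    # offset-corrected copy for the downstroke check: the rolling median
    # removes drift offsets without the overshoot a mean subtraction
    # creates around sharp transients
    med = (pd.Series(smooth)
           .rolling(win, center=True, min_periods=1).median().to_numpy())
    lobe_sig = smooth - med
    smooth = smooth - baseline
    thr = THRESHOLD_SCALE * _rolling_positive_quantile(
        smooth, win, THRESHOLD_QUANTILE)
    # floor the threshold at a fraction of the local maximum so it cannot
    # collapse in stretches where the positive part is mostly near zero
    local_max = (pd.Series(smooth)
                 .rolling(win, center=True, min_periods=1).max().to_numpy())
    thr = np.maximum(thr, THRESHOLD_FLOOR * np.maximum(local_max, 0.0))
    distance = max(int(round(REFRACTORY_S * fs)), 1)
    cand, _ = find_peaks(smooth, height=thr, distance=distance)
    if cand.size >= 5:
        # systolic upstrokes are homogeneous in height; an isolated huge
        # detection is an artifact transient (e.g. an abrupt step), not a beat
        heights = smooth[cand]
        cand = cand[heights <= HEIGHT_OUTLIER_FACTOR * np.median(heights)]
    if domain == "diff" and cand.size:
        # every systolic upstroke is followed by a diastolic downstroke;
        # an upward step artifact has no matching negative lobe
        look = max(int(round(DOWNSTROKE_S * fs)), 3)
        keep_mask = []
        for c in cand:
            seg = lobe_sig[c:min(c + look, lobe_sig.size)]
            keep_mask.append(
                seg.size < 3
                or seg.min() <= -DOWNSTROKE_FRACTION * lobe_sig[c])
        cand = cand[np.asarray(keep_mask)]
    if cand.size == 0:
        warnings.warn("no beats detected; window should be rejected",
                      stacklevel=2)
        return np.empty(0, dtype=int)

    # refine to the raw-waveform local maximum near each candidate
    r = max(int(round(REFINE_S * fs)), 1)
    y = rec.samples
    refined = []
    for c in cand:
        lo = max(c - r, 0)
        hi = min(c + r + 1, y.size)
        refined.append(lo + int(np.argmax(y[lo:hi])))
    peaks = np.unique(refined)

    # re-impose the refractory period after refinement
    kept = [int(peaks[0])]
    for p in peaks[1:]:
        if p - kept[-1] >= distance:
            kept.append(int(p))
    return np.asarray(kept, dtype=int)


def to_ibi(peaks: np.ndarray, fs_hz: float) -> IBISeries:
    """Convert beat indices to validated peak-to-peak intervals.

    Implausibly short intervals (< 0.3 s) are treated as false detections
    and merged into the neighbouring interval by dropping the extra beat.
    Intervals above 2.0 s, and intervals differing from the preceding
    valid interval by more than 75 %, are excluded from the series (the
    beats are kept, the interval leaves a gap).
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 2:
        raise ValueError("cannot form intervals: need at least 2 peaks")
    times = peaks / fs_hz

    # merge-out false peaks creating too-short intervals
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= IBI_MIN_S:
            kept.append(t)
    beat_times = np.asarray(kept)

    intervals, knots = [], []
    prev_valid: float | None = None
    for i in range(1, beat_times.size):
        iv = beat_times[i] - beat_times[i - 1]
        if iv >= IBI_MAX_S:
            prev_valid = None  # gap: restart the continuity check
            continue
        if prev_valid is not None and abs(iv - prev_valid) / prev_valid > MAX_RELATIVE_STEP:
            continue
        intervals.append(iv)
        knots.append(beat_times[i])
        prev_valid = iv
    return IBISeries(beat_times_s=beat_times,
                     intervals_s=np.asarray(intervals),
                     knot_times_s=np.asarray(knots),
                     source_fs_hz=fs_hz)


def preprocess(rec: PPGRecord, domain: str = "diff") -> IBISeries:
    """Full preprocessing chain: detect beats, form validated intervals."""
    peaks = detect_peaks(rec, domain=domain)
    if peaks.size < 2:
        raise ValueError("cannot form intervals: fewer than 2 beats detected")
    ibi = to_ibi(peaks, rec.fs_hz)
    if rec.t0_s != 0.0:
        ibi = IBISeries(beat_times_s=ibi.beat_times_s + rec.t0_s,
                        intervals_s=ibi.intervals_s,
                        knot_times_s=ibi.knot_times_s + rec.t0_s,
                        source_fs_hz=ibi.source_fs_hz)
    return ibi
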