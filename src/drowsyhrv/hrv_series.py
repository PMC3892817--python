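"""Evenly sampled HRV series via cubic-spline resampling, plus windowing.

FFT analysis needs equidistant samples, but P-P intervals arrive at the
(uneven) beat times.  The interval series is therefore interpolated with
a cubic spline through the (knot time, interval) pairs and evaluated on a
uniform grid — 7 Hz by default — spanning the first to last knot.  No
extrapolation beyond the knots is performed.

Analysis windows (1, 2 or 3 min) are cut on the resampled grid,
non-overlapping by default, so a 10-minute session yields ten 1-minute
windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from drowsyhrv.ppg_preprocess import IBI_MAX_S, IBI_MIN_S, IBISeries

__all__ = ["HRVSeries", "resample", "window"]

DEFAULT_FS_HZ = 7.0


@dataclass(frozen=True)
class HRVSeries:
    """Uniformly resampled interval series (seconds) at ``fs_hz``."""

    values: np.ndarray
    fs_hz: float
    start_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def duration_s(self) -> float:
        """Time spanned by the sample grid (first to last sample)."""
        return (self.values.size - 1) / self.fs_hz if self.values.size else 0.0

    @property
    def times_s(self) -> np.ndarray:
        return self.start_s + np.arange(self.values.size) / self.fs_hz


def resample(ibi: IBISeries, fs_hz: float = DEFAULT_FS_HZ,
             bc_type: str = "natural", clip: bool = True) -> HRVSeries:
    """Cubic-spline resample an interval series onto a uniform grid.

    The spline interpolates exactly through every (knot time, interval)
    pair; the grid starts at the first knot and ends at or before the
    last.  Spline overshoot outside the plausible interval range is
    clipped back into (0.3, 2.0) s when ``clip`` is set.

    Raises
    ------
    ValueError
        With fewer than 4 valid intervals (a cubic spline needs 4 knots).
    """
    knots = ibi.knot_times_s
    vals = ibi.intervals_s
    if knots.size < 4:
        raise ValueError("insufficient beats for spline: need at least "
                         "4 valid intervals")
    spline = CubicSpline(knots, vals, bc_type=bc_type)
    n = int(np.floor((knots[-1] - knots[0]) * fs_hz)) + 1
    grid = knots[0] + np.arange(n) / fs_hz
    out = spline(grid)
    if clip:
        out = np.clip(out, IBI_MIN_S + 1e-9, IBI_MAX_S - 1e-9)
    return HRVSeries(values=out, fs_hz=fs_hz, start_s=float(knots[0]))


def window(hrv: HRVSeries, length_s: float = 60.0,
           hop_s: float | None = None) -> list[HRVSeries]:
    """Cut an HRV series into consecutive analysis windows.

    ``hop_s`` defaults to ``length_s`` (non-overlapping).  Windows are
    ``round(length_s * fs)`` samples long; a record shorter than one
    window yields an empty list with a warning.
    """
    n_win = int(round(length_s * hrv.fs_hz))
    n_hop = n_win if hop_s is None else int(round(hop_s * hrv.fs_hz))
    if n_hop <= 0:
        raise ValueError("hop_s must be positive")
    out: list[HRVSeries] = []
    start = 0
    while start + n_win <= hrv.values.size:
        out.append(HRVSeries(values=hrv.values[start:start + n_win],
                             fs_hz=hrv.fs_hz,
                             start_s=hrv.start_s + start / hrv.fs_hz))
        start += n_hop
    if not out:
        warnings.warn("record shorter than one analysis window",
                      stacklevel=2)
    return out
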