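"""FFT-based power spectral density, HRV band powers and the LF/HF ratio.

The HRV spectrum is conventionally split into very-low-frequency
(0.003-0.04 Hz), low-frequency (0.04-0.15 Hz) and high-frequency
(0.15-0.4 Hz) bands; LF power reflects mixed sympathetic/parasympathetic
drive, HF power respiratory vagal drive, and their ratio LF/HF indexes
sympathovagal balance.

Estimator: the window mean is removed and a Hann taper applied; windows
of about two minutes and longer use Welch averaging (64 s segments, 50 %
overlap) to cut estimator variance, shorter windows a single-taper
periodogram.  Densities are one-sided and scaled so that the integral of
the PSD approximates the variance of the mean-removed window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram, welch

from drowsyhrv.hrv_series import HRVSeries

__all__ = ["BAND_EDGES_HZ", "BandPowers", "psd", "band_powers"]

#: closed HRV band intervals, Hz
BAND_EDGES_HZ: dict[str, tuple[float, float]] = {
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
}

#: minimum window duration for a meaningful LF estimate, seconds
MIN_WINDOW_S = 58.0
#: duration from which Welch averaging replaces the single periodogram
WELCH_FROM_S = 115.0
WELCH_SEGMENT_S = 64.0


@dataclass(frozen=True)
class BandPowers:
    """Integrated band powers (s^2) and the LF/HF ratio.

    ``lf_hf`` is NaN when the HF power is zero (the window must then be
    excluded from any LF/HF-based analysis).
    """

    vlf: float
    lf: float
    hf: float
    lf_hf: float
    band_edges: dict[str, tuple[float, float]]


def psd(hrv: HRVSeries) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectral density of an HRV window.

    Returns ``(freqs_hz, density)`` with density in s^2/Hz.  The mean is
    removed first, so adding a constant to the window leaves the result
    unchanged; a constant window yields an all-zero density.
    """
    x = hrv.values
    if hrv.duration_s < MIN_WINDOW_S:
        raise ValueError(
            f"window too short for spectral analysis: {hrv.duration_s:.1f} s "
            f"< {MIN_WINDOW_S:.0f} s")
    if hrv.duration_s >= WELCH_FROM_S:
        nperseg = min(int(round(WELCH_SEGMENT_S * hrv.fs_hz)), x.size)
        f, d = welch(x, fs=hrv.fs_hz, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="constant",
                     scaling="density")
    else:
        f, d = periodogram(x, fs=hrv.fs_hz, window="hann",
                           detrend="constant", scaling="density")
    return f, d


def band_powers(freqs: np.ndarray, density: np.ndarray) -> BandPowers:
    """Integrate a PSD over the VLF/LF/HF bands and form LF/HF.

    Trapezoidal integration over each closed band; a bin falling exactly
    on a shared band edge is credited to the lower band only.
    """
    freqs = np.asarray(freqs, dtype=float)
    density = np.asarray(density, dtype=float)
    powers: dict[str, float] = {}
    prev_hi: float | None = None
    for name, (lo, hi) in BAND_EDGES_HZ.items():
        if prev_hi is not None and lo == prev_hi:
            mask = (freqs > lo) & (freqs <= hi)
        else:
            mask = (freqs >= lo) & (freqs <= hi)
        powers[name] = (float(np.trapezoid(density[mask], freqs[mask]))
                        if mask.sum() >= 2 else 0.0)
        prev_hi = hi
    lf_hf = powers["lf"] / powers["hf"] if powers["hf"] > 0 else float("nan")
    return BandPowers(vlf=powers["vlf"], lf=powers["lf"], hf=powers["hf"],
                      lf_hf=lf_hf, band_edges=dict(BAND_EDGES_HZ))


def lf_hf_ratio(hrv: HRVSeries) -> float:
    """Convenience: LF/HF ratio of one window."""
    return band_powers(*psd(hrv)).lf_hf
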