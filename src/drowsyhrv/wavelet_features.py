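"""8-level Symlet-3 wavelet decomposition and the 43-value feature vector.

Drowsy-driver HRV is nonstationary — its spectral content drifts within a
window — which an FFT, with its global stationarity assumption, averages
away.  The discrete wavelet transform localises energy in both time and
dyadic frequency bands: a Mallat cascade with the near-symmetric Symlet-3
mother wavelet splits a 7 Hz HRV window into detail levels D1..D8 and the
approximation A8.  Level ``n`` covers ``(fs / 2**(n+1), fs / 2**n)`` Hz,
so D5-D7 straddle the classical LF band and A8+D8 the VLF region.

From each of the nine coefficient sets four statistics are taken —
wavelet Shannon entropy, mean, variance and kurtosis — plus a multiscale
spectral slope ``beta`` for each of the seven adjacent detail-level
pairs: 36 + 7 = 43 features per window.

Conventions (recorded in output metadata):

* entropy is the unnormalised wavelet Shannon entropy
  ``-sum(c**2 * log2(c**2))`` in bits, with ``0*log(0) := 0`` — an
  energy-weighted disorder measure, not a probability entropy;
* variance is the unbiased sample variance; kurtosis is the
  standardised fourth moment (non-excess; large Gaussian samples -> 3);
* ``beta`` for the pair (D(j+1), Dj) is
  ``log2(var(D(j+1))) - log2(var(Dj))``, the local slope of log-variance
  across one dyadic scale step;
* degenerate (zero-variance) levels impute kurtosis 3 and beta 0 with a
  warning — on real-like data they indicate an upstream failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from drowsyhrv.hrv_series import HRVSeries

__all__ = [
    "WaveletDecomposition",
    "decompose",
    "reconstruct",
    "level_frequency_range",
    "shannon_entropy",
    "moments",
    "multiscale_beta",
    "feature_vector",
    "FEATURE_NAMES",
    "N_LEVELS",
]

N_LEVELS = 8
WAVELET = "sym3"
BOUNDARY_MODE = "symmetric"
MIN_SAMPLES = 2 ** N_LEVELS

#: imputations for degenerate (zero-variance) coefficient sets
KURTOSIS_IMPUTE = 3.0  # Gaussian reference
BETA_IMPUTE = 0.0      # locally flat spectrum

_LEVELS = [f"A{N_LEVELS}"] + [f"D{i}" for i in range(N_LEVELS, 0, -1)]
_STATS = ["entropy", "mean", "variance", "kurtosis"]
_BETA_PAIRS = [(j + 1, j) for j in range(N_LEVELS - 1, 0, -1)]  # (8,7)..(2,1)

#: the 43 feature names, in fixed output order
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{lev}" for lev in _LEVELS for stat in _STATS
) + tuple(f"beta_D{a}D{b}" for a, b in _BETA_PAIRS)


@dataclass(frozen=True)
class WaveletDecomposition:
    """Coefficients of an 8-level DWT: details D1..D8 and approximation A8."""

    details: dict[int, np.ndarray]
    approximation: np.ndarray
    wavelet_name: str
    fs_hz: float
    mode: str
    input_length: int

    def level(self, name: str) -> np.ndarray:
        """Coefficients by level name, e.g. ``"D5"`` or ``"A8"``."""
        if name == f"A{N_LEVELS}":
            return self.approximation
        if name.startswith("D"):
            return self.details[int(name[1:])]
        raise KeyError(name)


def decompose(hrv: HRVSeries, wavelet: str = WAVELET,
              mode: str = BOUNDARY_MODE) -> WaveletDecomposition:
    """Mallat-cascade DWT of an HRV window to depth 8.

    A 1-minute window at 7 Hz (420 samples) qualifies; inputs shorter
    than ``2**8 = 256`` samples are rejected.
    """
    x = hrv.values
    if x.size < MIN_SAMPLES:
        raise ValueError(
            f"window too short for an {N_LEVELS}-level decomposition: "
            f"{x.size} < {MIN_SAMPLES} samples")
    with warnings.catch_warnings():
        # depth 8 deliberately exceeds pywt's boundary-effect heuristic
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, mode=mode, level=N_LEVELS)
    approx = coeffs[0]
    details = {N_LEVELS - i: c for i, c in enumerate(coeffs[1:])}
    return WaveletDecomposition(details=details, approximation=approx,
                                wavelet_name=wavelet, fs_hz=hrv.fs_hz,
                                mode=mode, input_length=x.size)


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse DWT; recovers the input to within floating-point error."""
    coeffs = [decomp.approximation] + [decomp.details[i]
                                       for i in range(N_LEVELS, 0, -1)]
    out = pywt.waverec(coeffs, decomp.wavelet_name, mode=decomp.mode)
    return out[:decomp.input_length]


def level_frequency_range(n: int, fs_hz: float) -> tuple[float, float]:
    """Frequency band (Hz) of detail level ``n``: ``(fs/2**(n+1), fs/2**n)``.

    At the 7 Hz HRV sampling rate, D1 covers 1.75-3.5 Hz and D5 covers
    0.109-0.219 Hz (the upper LF / lower HF region).
    """
    if not 1 <= n <= N_LEVELS:
        raise ValueError(f"level index must be in 1..{N_LEVELS}, got {n}")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    return fs_hz / 2 ** (n + 1), fs_hz / 2 ** n


def shannon_entropy(coeffs: np.ndarray) -> float:
    """Unnormalised wavelet Shannon entropy, ``-sum(c^2 log2 c^2)`` (bits).

    Zero coefficients contribute nothing (``0*log 0 := 0``); an all-zero
    set has entropy 0.  Not bounded like a probability entropy — its
    magnitude grows with signal energy, which is what makes it sensitive
    to the slow-trend energy drowsiness injects into A8.
    """
    c2 = np.asarray(coeffs, dtype=float) ** 2
    nz = c2[c2 > 0]
    if nz.size == 0:
        return 0.0
    return float(-np.sum(nz * np.log2(nz)))


def moments(coeffs: np.ndarray) -> tuple[float, float, float]:
    """Sample mean, unbiased variance and non-excess kurtosis.

    Kurtosis is the standardised fourth moment ``m4 / m2**2`` (a large
    Gaussian sample gives ~3).  A zero-variance set has undefined
    kurtosis, imputed as 3.0 with a warning.
    """
    c = np.asarray(coeffs, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 coefficients for kurtosis")
    mean = float(np.mean(c))
    var = float(np.var(c, ddof=1))
    m2 = float(np.mean((c - mean) ** 2))
    if m2 == 0.0:
        warnings.warn("zero-variance coefficient set: kurtosis imputed as "
                      f"{KURTOSIS_IMPUTE}", stacklevel=2)
        return mean, var, KURTOSIS_IMPUTE
    m4 = float(np.mean((c - mean) ** 4))
    return mean, var, m4 / m2 ** 2


def multiscale_beta(decomp: WaveletDecomposition,
                    pair: tuple[int, int]) -> float:
    """Local log-variance slope between adjacent detail levels.

    ``beta = log2(var(D(j+1))) - log2(var(Dj))`` for ``pair=(j+1, j)``:
    positive when energy grows toward coarser (lower-frequency) scales,
    as in 1/f-like HRV.  Unchanged under global rescaling of the input.
    """
    hi, lo = pair
    if hi != lo + 1:
        raise ValueError("pair must be adjacent levels (j+1, j)")
    v_hi = float(np.var(decomp.details[hi], ddof=1))
    v_lo = float(np.var(decomp.details[lo], ddof=1))
    if v_hi == 0.0 or v_lo == 0.0:
        warnings.warn("zero variance in a detail level: beta imputed as "
                      f"{BETA_IMPUTE}", stacklevel=2)
        return BETA_IMPUTE
    return float(np.log2(v_hi) - np.log2(v_lo))


def feature_vector(hrv: HRVSeries, wavelet: str = WAVELET,
                   mode: str = BOUNDARY_MODE) -> dict[str, float]:
    """The 43 named wavelet features of one HRV window.

    Four statistics for each of A8, D8..D1 (36 values) plus seven
    multiscale beta slopes for the adjacent detail pairs (D8,D7)..(D2,D1),
    returned in the fixed :data:`FEATURE_NAMES` order.
    """
    decomp = decompose(hrv, wavelet=wavelet, mode=mode)
    out: dict[str, float] = {}
    for lev in _LEVELS:
        c = decomp.level(lev)
        mean, var, kurt = moments(c)
        out[f"entropy_{lev}"] = shannon_entropy(c)
        out[f"mean_{lev}"] = mean
        out[f"variance_{lev}"] = var
        out[f"kurtosis_{lev}"] = kurt
    for a, b in _BETA_PAIRS:
        out[f"beta_D{a}D{b}"] = multiscale_beta(decomp, (a, b))
    return out
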