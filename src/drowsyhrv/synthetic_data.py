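"""Ground-truthed simulators for inter-beat intervals, PPG waveforms and PERCLOS.

The study data this package targets — short driving sessions with an alert
and a drowsy phase, recorded with a 40 Hz reflective finger PPG — is not
publicly available, so every downstream stage is exercised against
simulations with known ground truth instead.

The inter-beat-interval (IBI) generator superimposes sinusoidal modulation
at representative VLF/LF/HF frequencies on a base interval, plus optional
white beat-to-beat jitter.  The "drowsy" regime is a sustained,
nonstationary state: the mean interval is elevated (drowsiness slows the
heart) and both the mean interval and the LF modulation amplitude follow
seeded piecewise-linear drift schedules, reflecting the sympathetic
activation and time-varying dynamics reported for sleepy drivers.  The
PPG renderer places an
asymmetric raised-cosine pulse at each beat and can add slow baseline
wander and sparse steering-wheel motion artifacts (smoothed steps and
ramp bumps).  PERCLOS traces are drawn uniformly inside the band each
driving state occupies (alert: 0–30 %, drowsy: 30–40 % eyelid closure).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_ibi",
    "render_ppg",
    "simulate_perclos",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated driving session.

    Amplitudes are in seconds of interval modulation; frequencies in Hz.
    The stationary defaults describe an alert driver at ~67 bpm with
    balanced LF/HF modulation.

    ``nonstationary=True`` selects the drowsy regime: the mean interval
    is raised by ``drowsy_mean_offset_s`` (heart rate slows when drowsy)
    and both the mean interval and the LF amplitude follow seeded
    piecewise-linear drift schedules with ``drift_segment_s`` breakpoints
    — the mean wanders within ±``drift_wander_s`` and the LF amplitude
    between ``drowsy_lf_range`` times its alert value — so every analysis
    window contains genuine within-window drift.  Setting ``lf_amp_end``
    / ``mean_ibi_end_s`` overrides the random schedules with simple
    linear ramps from the base values (useful for controlled tests).

    Real alert HRV is not perfectly stationary either: ``mean_wander_s``
    and ``lf_variability`` add mild piecewise-linear wander of the mean
    interval (± seconds) and of the LF amplitude (fractional, so 0.4
    means the amplitude drifts between 0.6x and 1.4x) to the stationary
    regime.  Both default to 0 so that explicitly configured amplitudes
    produce exactly the requested modulation.
    """

    duration_s: float = 615.0
    mean_ibi_s: float = 0.9
    vlf_amp: float = 0.01
    lf_amp: float = 0.03
    hf_amp: float = 0.03
    vlf_freq_hz: float = 0.02
    lf_freq_hz: float = 0.1
    hf_freq_hz: float = 0.3
    jitter_s: float = 0.005
    nonstationary: bool = False
    lf_amp_end: float | None = None
    mean_ibi_end_s: float | None = None
    drowsy_mean_offset_s: float = 0.1
    drowsy_lf_range: tuple[float, float] = (1.0, 3.0)
    drift_wander_s: float = 0.05
    drift_segment_s: float = 120.0
    mean_wander_s: float = 0.0
    lf_variability: float = 0.0
    artifact_rate_per_min: float = 0.0
    baseline_wander_amp: float = 0.0
    baseline_wander_freq_hz: float = 0.05
    pulse_width_s: float = 0.35
    pulse_rise_frac: float = 0.3
    pulse_amp: float = 1.0
    random_phases: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not 0.3 <= self.mean_ibi_s <= 2.0:
            raise ValueError("mean_ibi_s must lie in [0.3, 2.0] s")
        for name in ("vlf_amp", "lf_amp", "hf_amp", "jitter_s",
                     "artifact_rate_per_min", "baseline_wander_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.pulse_rise_frac < 1:
            raise ValueError("pulse_rise_frac must lie in (0, 1)")

    def drowsy(self) -> "SimConfig":
        """Return the nonstationary (drowsy) variant of this config."""
        return replace(self, nonstationary=True)


@dataclass(frozen=True)
class GroundTruth:
    """True beat times and intervals of a simulated session."""

    beat_times_s: np.ndarray
    ibi_s: np.ndarray
    true_lf_hf: float
    label: Literal["alert", "drowsy"]

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times_s, dtype=float)
        ibi = np.asarray(self.ibi_s, dtype=float)
        object.__setattr__(self, "beat_times_s", bt)
        object.__setattr__(self, "ibi_s", ibi)
        if bt.size and np.any(np.diff(bt) <= 0):
            raise ValueError("beat_times_s must be strictly increasing")
        if ibi.size != max(bt.size - 1, 0):
            raise ValueError("ibi_s must hold one interval per beat pair")
        if ibi.size and not np.allclose(ibi, np.diff(bt), atol=1e-9):
            raise ValueError("ibi_s inconsistent with beat_times_s")


def _drift_schedules(cfg: SimConfig, rng: np.random.Generator):
    """Piecewise-linear (time, value) schedules for mean IBI and LF amplitude.

    Stationary configs return constant schedules.  Nonstationary configs
    with explicit ``lf_amp_end`` / ``mean_ibi_end_s`` ramp linearly from
    the base values; otherwise seeded random breakpoints every
    ``drift_segment_s`` realise the drowsy drift described in
    :class:`SimConfig`.
    """
    t_ends = np.array([0.0, cfg.duration_s])
    mean_sched = (t_ends, np.full(2, cfg.mean_ibi_s))
    lf_sched = (t_ends, np.full(2, cfg.lf_amp))
    if not cfg.nonstationary:
        if cfg.mean_wander_s > 0 or cfg.lf_variability > 0:
            n_seg = max(int(np.ceil(cfg.duration_s / cfg.drift_segment_s)), 1)
            t_knots = np.linspace(0.0, cfg.duration_s, n_seg + 1)
            mean_vals = cfg.mean_ibi_s + rng.uniform(
                -cfg.mean_wander_s, cfg.mean_wander_s, size=n_seg + 1)
            lf_vals = cfg.lf_amp * rng.uniform(
                1.0 - cfg.lf_variability, 1.0 + cfg.lf_variability,
                size=n_seg + 1)
            return (t_knots, mean_vals), (t_knots, lf_vals)
        return mean_sched, lf_sched
    if cfg.lf_amp_end is not None or cfg.mean_ibi_end_s is not None:
        lf_end = cfg.lf_amp_end if cfg.lf_amp_end is not None else cfg.lf_amp
        mean_end = (cfg.mean_ibi_end_s if cfg.mean_ibi_end_s is not None
                    else cfg.mean_ibi_s)
        return ((t_ends, np.array([cfg.mean_ibi_s, mean_end])),
                (t_ends, np.array([cfg.lf_amp, lf_end])))
    n_seg = max(int(np.ceil(cfg.duration_s / cfg.drift_segment_s)), 1)
    t_knots = np.linspace(0.0, cfg.duration_s, n_seg + 1)
    base = cfg.mean_ibi_s + cfg.drowsy_mean_offset_s
    mean_vals = base + rng.uniform(-cfg.drift_wander_s, cfg.drift_wander_s,
                                   size=n_seg + 1)
    lo, hi = cfg.drowsy_lf_range
    lf_vals = cfg.lf_amp * rng.uniform(lo, hi, size=n_seg + 1)
    return (t_knots, mean_vals), (t_knots, lf_vals)


def _modulation(cfg: SimConfig, t: float, phases: Sequence[float],
                mean_sched, lf_sched) -> float:
    """Instantaneous IBI (seconds) at time ``t``, before jitter."""
    mean = float(np.interp(t, *mean_sched))
    lf_amp = float(np.interp(t, *lf_sched))
    two_pi = 2.0 * np.pi
    return (
        mean
        + cfg.vlf_amp * np.sin(two_pi * cfg.vlf_freq_hz * t + phases[0])
        + lf_amp * np.sin(two_pi * cfg.lf_freq_hz * t + phases[1])
        + cfg.hf_amp * np.sin(two_pi * cfg.hf_freq_hz * t + phases[2])
    )


def simulate_ibi(config: SimConfig) -> GroundTruth:
    """Simulate a beat sequence whose intervals follow the configured modulation.

    Beats are generated iteratively: the next beat falls one instantaneous
    IBI after the current one, with optional white jitter.  The recorded
    ``true_lf_hf`` is the power ratio implied by the modulation amplitudes,
    ``lf_amp**2 / hf_amp**2`` (time-averaged LF amplitude for nonstationary
    sessions); it is NaN when ``hf_amp`` is zero.

    Raises
    ------
    ValueError
        If the configured amplitudes can drive an interval to zero or
        below (the modulation sum reaches the mean interval).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mean_sched, lf_sched = _drift_schedules(cfg, rng)
    max_lf = float(np.max(lf_sched[1]))
    min_mean = float(np.min(mean_sched[1]))
    max_amp = cfg.vlf_amp + max_lf + cfg.hf_amp
    if max_amp >= min_mean - 4.0 * cfg.jitter_s:
        raise ValueError(
            "modulation amplitudes too large: the summed amplitude "
            f"{max_amp:.3f} s can drive intervals at mean {min_mean:.3f} s "
            "to zero or below"
        )
    if cfg.random_phases:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    else:
        phases = np.zeros(3)

    beats = [0.0]
    t = 0.0
    while True:
        ibi = float(_modulation(cfg, t, phases, mean_sched, lf_sched))
        if cfg.jitter_s > 0:
            ibi += float(rng.normal(0.0, cfg.jitter_s))
        if ibi <= 0:
            raise ValueError("generated a non-positive interval; reduce "
                             "amplitudes or jitter")
        nxt = t + ibi
        if nxt > cfg.duration_s + 1e-12:
            break
        beats.append(nxt)
        t = nxt

    beat_times = np.asarray(beats)
    if cfg.hf_amp > 0:
        # time-averaged LF amplitude of the (piecewise-linear) schedule
        lf_eff = float(np.trapezoid(lf_sched[1], lf_sched[0]) / cfg.duration_s)
        true_lf_hf = (lf_eff / cfg.hf_amp) ** 2
    else:
        true_lf_hf = float("nan")
    label = "drowsy" if cfg.nonstationary else "alert"
    return GroundTruth(beat_times, np.diff(beat_times), true_lf_hf, label)


def _pulse_template(fs_hz: float, width_s: float, rise_frac: float,
                    amp: float) -> tuple[np.ndarray, int]:
    """Asymmetric raised-cosine pulse; returns (samples, index of maximum)."""
    rise = rise_frac * width_s
    decay = width_s - rise
    n_rise = max(int(round(rise * fs_hz)), 1)
    n_decay = max(int(round(decay * fs_hz)), 1)
    up = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_rise + 1) / n_rise))
    down = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, n_decay + 1) / n_decay))
    tpl = amp * np.concatenate([up, down])
    return tpl, n_rise


def render_ppg(gt: GroundTruth, fs_hz: float = 40.0,
               config: SimConfig | None = None):
    """Render a PPG waveform from ground-truth beats.

    Each beat contributes one pulse whose maximum falls on the sample
    nearest the true beat time.  Baseline wander is a slow sinusoid;
    motion artifacts (rate ``artifact_rate_per_min``) are an even mix of
    smoothed level steps and triangular ramp bumps — the additive,
    low-frequency disturbances a first-order difference suppresses.

    Returns
    -------
    (PPGRecord, np.ndarray)
        The waveform record and the true beat sample indices.
    """
    from drowsyhrv.ppg_preprocess import PPGRecord

    cfg = config if config is not None else SimConfig()
    if fs_hz < 20:
        raise ValueError("fs_hz must be at least 20 Hz to resolve the pulse")
    duration = cfg.duration_s if gt.beat_times_s.size == 0 else max(
        cfg.duration_s, float(gt.beat_times_s[-1]) + cfg.pulse_width_s)
    n = int(np.ceil(duration * fs_hz)) + 1
    t = np.arange(n) / fs_hz
    y = np.zeros(n)

    tpl, i_max = _pulse_template(fs_hz, cfg.pulse_width_s,
                                 cfg.pulse_rise_frac, cfg.pulse_amp)
    beat_idx = np.round(gt.beat_times_s * fs_hz).astype(int)
    for b in beat_idx:
        start = b - i_max
        lo = max(start, 0)
        hi = min(start + tpl.size, n)
        if hi > lo:
            y[lo:hi] += tpl[lo - start:hi - start]

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    if cfg.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi) if cfg.random_phases else -np.pi / 2
        y += cfg.baseline_wander_amp * np.sin(
            2 * np.pi * cfg.baseline_wander_freq_hz * t + phase)

    n_events = rng.poisson(cfg.artifact_rate_per_min * duration / 60.0)
    for _ in range(n_events):
        t0 = rng.uniform(0.05 * duration, 0.95 * duration)
        height = rng.uniform(0.3, 0.8) * cfg.pulse_amp * rng.choice([-1.0, 1.0])
        if rng.random() < 0.5:
            # smoothed level step, ~0.5 s transition (hand shifting grip)
            y += height * 0.5 * (1.0 + np.tanh((t - t0) / 0.15))
        else:
            # triangular ramp bump: up then down over 2*d
            d = rng.uniform(0.4, 0.8)
            bump = np.clip(1.0 - np.abs(t - t0) / d, 0.0, None)
            y += height * bump

    keep = (beat_idx >= 0) & (beat_idx < n)
    return PPGRecord(samples=y, fs_hz=fs_hz, t0_s=0.0), beat_idx[keep]


def simulate_perclos(label: Literal["alert", "drowsy"], n_windows: int,
                     seed: int = 0) -> np.ndarray:
    """Draw per-window PERCLOS fractions for a driving state.

    Alert windows fall uniformly in [0, 0.30), drowsy windows in
    [0.30, 0.40] — the eyelid-closure bands that delimit the two states.
    """
    if n_windows < 0:
        raise ValueError("n_windows must be non-negative")
    rng = np.random.default_rng(seed)
    if label == "alert":
        return rng.uniform(0.0, 0.30, size=n_windows)
    if label == "drowsy":
        return rng.uniform(0.30, 0.40, size=n_windows)
    raise ValueError(f"unknown label {label!r}")
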