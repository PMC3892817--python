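"""Plain-text readers/writers for PPG, beat, HRV and feature tables.

All formats are commented CSV: lines starting with ``#`` carry metadata
(sampling rate, seed, conventions) and are skipped on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from drowsyhrv.ppg_preprocess import IBISeries, PPGRecord

__all__ = [
    "write_ppg_csv",
    "read_ppg_csv",
    "write_ibi_csv",
    "read_ibi_csv",
    "write_perclos_csv",
    "read_perclos_csv",
]


def _write_with_header(path: Path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def write_ppg_csv(path: str | Path, rec: PPGRecord, meta: dict | None = None) -> None:
    """Write a PPG record as 2-column CSV (time_s, amplitude)."""
    t = rec.t0_s + np.arange(rec.samples.size) / rec.fs_hz
    df = pd.DataFrame({"time_s": t, "amplitude": rec.samples})
    _write_with_header(Path(path), df, {"fs_hz": rec.fs_hz, **(meta or {})})


def read_ppg_csv(path: str | Path, fs_hz: float | None = None) -> PPGRecord:
    """Read a PPG CSV; the sampling rate comes from the time column unless given."""
    df = pd.read_csv(path, comment="#")
    if "amplitude" not in df.columns:  # raw single-column amplitude file
        samples = df.iloc[:, -1].to_numpy(dtype=float)
        if fs_hz is None:
            raise ValueError("fs_hz required for a bare amplitude column")
        return PPGRecord(samples=samples, fs_hz=fs_hz, t0_s=0.0)
    t = df["time_s"].to_numpy(dtype=float)
    if fs_hz is None:
        fs_hz = 1.0 / float(np.median(np.diff(t)))
    return PPGRecord(samples=df["amplitude"].to_numpy(dtype=float),
                     fs_hz=fs_hz, t0_s=float(t[0]))


def write_ibi_csv(path: str | Path, ibi: IBISeries, meta: dict | None = None) -> None:
    """Write validated intervals as CSV (knot_time_s, interval_s)."""
    df = pd.DataFrame({"knot_time_s": ibi.knot_times_s,
                       "interval_s": ibi.intervals_s})
    _write_with_header(Path(path), df,
                       {"source_fs_hz": ibi.source_fs_hz, **(meta or {})})


def read_ibi_csv(path: str | Path, source_fs_hz: float = 40.0) -> IBISeries:
    df = pd.read_csv(path, comment="#")
    knots = df["knot_time_s"].to_numpy(dtype=float)
    return IBISeries(beat_times_s=knots, intervals_s=df["interval_s"].to_numpy(dtype=float),
                     knot_times_s=knots, source_fs_hz=source_fs_hz)


def write_perclos_csv(path: str | Path, perclos: np.ndarray,
                      meta: dict | None = None) -> None:
    df = pd.DataFrame({"window_id": np.arange(len(perclos)),
                       "perclos": np.asarray(perclos, dtype=float)})
    _write_with_header(Path(path), df, meta or {})


def read_perclos_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
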