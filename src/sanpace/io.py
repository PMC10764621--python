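"""Plain-text readers and writers for traces, RR series and tables.

All on-disk formats are two-or-three-column CSV (vendor binary
electrophysiology formats are deliberately not parsed; convert upstream
and declare units in the run configuration).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import RRSeries, VoltageTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_rr",
    "write_rr",
    "read_receptor_list",
]

_UNIFORMITY_PPM = 1.0


def _load_numeric_csv(path: str | Path, n_cols: int) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    # header optional: if the first row parsed as column names is numeric,
    # re-read headerless
    try:
        [float(c) for c in df.columns[:n_cols]]
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         header=None)
    except (TypeError, ValueError):
        pass
    if df.shape[1] < n_cols:
        raise ValueError(f"{path}: expected at least {n_cols} columns")
    return df


def read_trace(path: str | Path, time_unit: str = "s",
               voltage_unit: str = "mV") -> VoltageTrace:
    """Read a two-column (time, voltage) text/CSV trace.

    Sampling must be uniform to within 1 ppm jitter; rows with non-finite
    values are dropped with a warning (count kept in metadata).  Supported
    units: time ``s``/``ms``, voltage ``mV``/``V``.
    """
    df = _load_numeric_csv(path, 2)
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(float)
    v = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(float)
    finite = np.isfinite(t) & np.isfinite(v)
    n_dropped = int((~finite).sum())
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} non-finite rows",
                      stacklevel=2)
        t, v = t[finite], v[finite]
    if t.size < 2:
        raise ValueError(f"{path}: fewer than 2 usable samples")

    scale_t = {"s": 1.0, "ms": 1e-3}.get(time_unit)
    scale_v = {"mV": 1.0, "V": 1e3}.get(voltage_unit)
    if scale_t is None or scale_v is None:
        raise ValueError("units: time must be s/ms, voltage mV/V")
    t = t * scale_t

    dt = np.diff(t)
    dt0 = float(np.median(dt))
    # dropped rows leave integer-multiple gaps on an otherwise uniform
    # grid; anything else is jitter and gets rejected
    tol = _UNIFORMITY_PPM * 1e-6 * dt0 + 1e-12
    multiples = np.round(dt / dt0) if dt0 > 0 else np.zeros_like(dt)
    if dt0 <= 0 or np.any(multiples < 1) or \
            np.any(np.abs(dt - multiples * dt0) > tol):
        raise ValueError(
            f"{path}: non-uniform sampling beyond 1 ppm tolerance; "
            "resample before analysis")
    return VoltageTrace(sampling_interval=dt0, samples=v * scale_v,
                        metadata={"path": str(path),
                                  "n_dropped_rows": n_dropped})


def write_trace(trace: VoltageTrace, path: str | Path) -> None:
    """Write a trace as two-column CSV (time_s, vm_mV), round-trip safe."""
    df = pd.DataFrame({"time_s": trace.times, "vm_mV": trace.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def read_rr(path: str | Path) -> RRSeries:
    """Read an RR series CSV (beat_time_s, rr_ms[, activity][, period])."""
    df = _load_numeric_csv(path, 2)
    cols = {str(c).lower(): c for c in df.columns}
    t_col = cols.get("beat_time_s", df.columns[0])
    rr_col = cols.get("rr_ms", df.columns[1])
    activity = df[cols["activity"]].to_numpy() if "activity" in cols else None
    period = df[cols["period"]].to_numpy() if "period" in cols else None
    return RRSeries(
        beat_times_s=pd.to_numeric(df[t_col]).to_numpy(float),
        rr_ms=pd.to_numeric(df[rr_col]).to_numpy(float),
        activity=activity, period_labels=period,
        metadata={"path": str(path)})


def write_rr(rr: RRSeries, path: str | Path) -> None:
    """Write an RR series as CSV (beat_time_s, rr_ms[, period])."""
    data = {"beat_time_s": rr.beat_times_s, "rr_ms": rr.rr_ms}
    if rr.period_labels is not None:
        data["period"] = rr.period_labels
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_receptor_list(path: str | Path) -> list[str]:
    """Read a receptor annotation list: one gene id per line, '#' comments."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    if not ids:
        raise ValueError(f"{path}: empty receptor list")
    return ids
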