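"""Spontaneous action-potential segmentation and morphology quantification.

Operational definitions (standard for sinoatrial pacemaker-cell recordings):

* **MDP** — the most negative membrane potential between successive APs.
* **TOP** (take-off potential) — the potential at the last upward crossing
  of 10% of the cycle's maximum dV/dt before that maximum.
* **EDDR** (early diastolic depolarization rate) — the mean dV/dt over the
  10-50% portion of the MDP-to-TOP interval (time interpretation by
  default; a voltage-interval interpretation is available for sensitivity
  analysis).
* **APD50** — time between the half-amplitude crossings of upstroke and
  repolarization.
* **Amplitude** — peak minus MDP; **firing rate** — 60000 / mean cycle
  length (ms); cycles run MDP-to-MDP.

All threshold crossings use linear interpolation between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, savgol_filter

from .datatypes import VoltageTrace

__all__ = [
    "APConfig",
    "APCycle",
    "APParameters",
    "estimate_dvdt",
    "detect_aps",
    "segment_cycles",
    "compute_top",
    "compute_eddr",
    "compute_apd50",
    "summarize_window",
    "extract_cycles",
    "cycles_to_frame",
]


@dataclass(frozen=True)
class APConfig:
    """Tunable thresholds of the AP analysis chain.

    ``smoothing_window_ms`` sets the Savitzky-Golay differentiator window
    (1 ms default, polynomial order 3); ``detect_threshold_frac`` is the
    fraction of the robust global dV/dt maximum used for upstroke detection;
    ``top_fraction`` the per-cycle dV/dt fraction defining the take-off
    potential; ``eddr_lo``/``eddr_hi`` the bounds of the EDDR averaging
    window within the MDP-to-TOP interval.
    """

    smoothing_window_ms: float = 1.0
    smoothing_polyorder: int = 3
    detect_smooth_ms: float = 3.0
    mdp_smooth_ms: float = 5.0
    detect_threshold_frac: float = 0.25
    refractory_ms: float = 40.0
    min_dvdt_mV_per_ms: float = 1.0
    top_fraction: float = 0.10
    eddr_lo: float = 0.10
    eddr_hi: float = 0.50
    eddr_interval: str = "time"  # or "voltage"
    min_valid_cycles: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")
        if not 0 <= self.eddr_lo < self.eddr_hi <= 1.0:
            raise ValueError("need 0 <= eddr_lo < eddr_hi <= 1")
        if self.eddr_interval not in ("time", "voltage"):
            raise ValueError("eddr_interval must be 'time' or 'voltage'")


@dataclass
class APCycle:
    """Landmarks and derived parameters for one MDP-to-MDP cycle.

    Invalid cycles keep their landmarks but carry ``valid=False`` with the
    reason; summaries exclude them.
    """

    mdp_time_s: float
    mdp_mV: float
    peak_time_s: float
    peak_mV: float
    next_mdp_time_s: float
    dvdt_max_mV_per_ms: float
    dvdt_max_time_s: float
    top_time_s: float = np.nan
    top_mV: float = np.nan
    apd50_ms: float = np.nan
    eddr_mV_per_ms: float = np.nan
    valid: bool = True
    invalid_reason: str = ""
    # sample indices, used internally by the landmark passes
    _idx: dict = field(default_factory=dict, repr=False)

    @property
    def cycle_length_ms(self) -> float:
        return (self.next_mdp_time_s - self.mdp_time_s) * 1000.0

    @property
    def amplitude_mV(self) -> float:
        return self.peak_mV - self.mdp_mV

    def invalidate(self, reason: str) -> None:
        if self.valid:
            self.valid = False
            self.invalid_reason = reason


@dataclass(frozen=True)
class APParameters:
    """Window summary: per-parameter means over valid cycles."""

    firing_rate_bpm: float
    amplitude_mV: float
    apd50_ms: float
    dvdt_max_mV_per_ms: float
    mdp_mV: float
    top_mV: float
    eddr_mV_per_ms: float
    n_cycles: int
    n_invalid: int
    window: str = ""


# ---------------------------------------------------------------------------

def _savgol_deriv(samples: np.ndarray, dt_ms: float, window_ms: float,
                  polyorder: int) -> np.ndarray:
    wl = int(round(window_ms / dt_ms))
    wl = max(wl | 1, (polyorder + 2) | 1)  # odd and longer than the order
    if wl > samples.size:
        raise ValueError("smoothing window longer than trace")
    return savgol_filter(samples, wl, polyorder, deriv=1, delta=dt_ms,
                         mode="interp")


def estimate_dvdt(trace: VoltageTrace, config: APConfig = APConfig()
                  ) -> np.ndarray:
    """First derivative of the trace in mV/ms via a Savitzky-Golay
    smoothing differentiator (edge samples from the edge polynomial fits)."""
    return _savgol_deriv(trace.samples, trace.sampling_interval * 1000.0,
                         config.smoothing_window_ms,
                         config.smoothing_polyorder)


def detect_aps(trace: VoltageTrace, dvdt: np.ndarray,
               config: APConfig = APConfig()) -> np.ndarray:
    """Upstroke anchors: sample indices of each cycle's dV/dt maximum.

    The detection threshold is ``detect_threshold_frac`` of a *robust*
    global maximum (median of candidate upstroke peak heights), so one
    unusually large AP does not mask the rest.  Peak finding runs on an
    extra-smoothed derivative (``detect_smooth_ms``) so noise excursions
    neither trigger spurious anchors nor drag an anchor onto a noise
    maximum.  Returns an empty array with a warning when nothing crosses
    ``min_dvdt_mV_per_ms``.
    """
    dt_ms = trace.sampling_interval * 1000.0
    distance = max(int(config.refractory_ms / dt_ms), 1)
    floor = config.min_dvdt_mV_per_ms
    smooth = _savgol_deriv(trace.samples, dt_ms, config.detect_smooth_ms,
                           config.smoothing_polyorder)
    if smooth.size == 0 or np.nanmax(smooth) < floor:
        warnings.warn("no action potentials detected", stacklevel=2)
        return np.array([], dtype=int)

    first, _ = find_peaks(smooth, height=max(
        config.detect_threshold_frac * float(np.nanmax(smooth)), floor),
        distance=distance)
    if first.size == 0:
        warnings.warn("no action potentials detected", stacklevel=2)
        return np.array([], dtype=int)
    robust_max = float(np.median(smooth[first]))
    thr = max(config.detect_threshold_frac * robust_max, floor)
    anchors, _ = find_peaks(smooth, height=thr, distance=distance)
    if anchors.size == 0:
        warnings.warn("no action potentials detected", stacklevel=2)
    return anchors


def segment_cycles(trace: VoltageTrace, dvdt: np.ndarray,
                   anchors: np.ndarray,
                   config: APConfig = APConfig()) -> list[APCycle]:
    """MDP-to-MDP cycles from upstroke anchors.

    The MDP between anchors i and i+1 is the minimum potential in that
    inter-anchor interval, located on a lightly smoothed copy of the trace
    (``mdp_smooth_ms`` moving average) so white noise does not bias the
    most-negative-sample search toward noise minima; the MDP voltage and
    the peak are read from the raw trace at the located samples.
    Each complete cycle runs from one MDP to the next and contains one
    anchor; first and last partial cycles are discarded, so n anchors
    yield at most n-2 cycles.
    """
    anchors = np.asarray(anchors, dtype=int)
    if anchors.size < 3:
        raise ValueError("need at least 3 upstroke anchors to segment")
    if np.any(np.diff(anchors) <= 0):
        raise ValueError("anchor times must be strictly increasing")
    v = trace.samples
    dt = trace.sampling_interval
    dt_ms = dt * 1000.0

    wl = max(int(round(config.mdp_smooth_ms / dt_ms)), 1)
    v_smooth = uniform_filter1d(v, wl, mode="nearest") if wl > 1 else v
    mdp_idx = np.array([a + int(np.argmin(v_smooth[a:b]))
                        for a, b in zip(anchors[:-1], anchors[1:])])
    cycles: list[APCycle] = []
    for j in range(mdp_idx.size - 1):
        m0, m1 = int(mdp_idx[j]), int(mdp_idx[j + 1])
        anchor = int(anchors[j + 1])
        pk = anchor + int(np.argmax(v[anchor:m1 + 1]))
        cyc = APCycle(
            mdp_time_s=m0 * dt, mdp_mV=float(v[m0]),
            peak_time_s=pk * dt, peak_mV=float(v[pk]),
            next_mdp_time_s=m1 * dt,
            dvdt_max_mV_per_ms=float(dvdt[anchor]),
            dvdt_max_time_s=anchor * dt,
            _idx={"mdp": m0, "anchor": anchor, "peak": pk, "next_mdp": m1},
        )
        if not (cyc.mdp_mV <= cyc.peak_mV):
            cyc.invalidate("ordering: mdp above peak")
        cycles.append(cyc)
    return cycles


def _interp_crossing(t0: float, dt: float, y0: float, y1: float,
                     level: float) -> float:
    """Time of the linear-interpolated crossing of ``level`` between two
    samples at t0 and t0+dt."""
    if y1 == y0:
        return t0
    return t0 + dt * (level - y0) / (y1 - y0)


def compute_top(cycle: APCycle, trace: VoltageTrace, dvdt: np.ndarray,
                config: APConfig = APConfig()) -> None:
    """Take-off potential: V at the last upward crossing of
    ``top_fraction`` x (this cycle's dV/dt max) before the dV/dt maximum."""
    if not cycle.valid:
        return
    dt = trace.sampling_interval
    m0, anchor = cycle._idx["mdp"], cycle._idx["anchor"]
    thr = config.top_fraction * cycle.dvdt_max_mV_per_ms
    seg = dvdt[m0:anchor + 1]
    below = seg[:-1] < thr
    above = seg[1:] >= thr
    hits = np.nonzero(below & above)[0]
    if hits.size == 0:
        cycle.invalidate("no_top_crossing")
        return
    i = int(hits[-1]) + m0  # last upward crossing before the maximum
    t = _interp_crossing(i * dt, dt, dvdt[i], dvdt[i + 1], thr)
    cycle.top_time_s = t
    cycle.top_mV = float(np.interp(t, [i * dt, (i + 1) * dt],
                                   [trace.samples[i], trace.samples[i + 1]]))
    if not (cycle.mdp_mV <= cycle.top_mV <= cycle.peak_mV):
        cycle.invalidate("ordering: mdp <= top <= peak violated")


def _mean_dvdt_between(dvdt: np.ndarray, dt: float, t1: float, t2: float
                       ) -> float:
    """Trapezoidal mean of dV/dt over [t1, t2], with linear interpolation
    at the window edges."""
    n = dvdt.size
    ts = np.arange(n) * dt
    i1, i2 = int(np.ceil(t1 / dt)), int(np.floor(t2 / dt))
    i1, i2 = max(i1, 0), min(i2, n - 1)
    grid = np.concatenate(([t1], ts[i1:i2 + 1], [t2]))
    vals = np.interp(grid, ts, dvdt)
    return float(np.trapezoid(vals, grid) / (t2 - t1))


def compute_eddr(cycle: APCycle, trace: VoltageTrace, dvdt: np.ndarray,
                 config: APConfig = APConfig()) -> None:
    """Early diastolic depolarization rate: mean dV/dt over the
    ``eddr_lo``-``eddr_hi`` (default 10-50%) span of the MDP-to-TOP
    interval.  In the default ``time`` mode the span is taken on the time
    axis; in ``voltage`` mode it is delimited by the corresponding
    fractional voltage levels between MDP and TOP."""
    if not cycle.valid or not np.isfinite(cycle.top_time_s):
        return
    dt = trace.sampling_interval
    if config.eddr_interval == "time":
        delta = cycle.top_time_s - cycle.mdp_time_s
        if delta < 5 * dt:
            cycle.invalidate("mdp_to_top_interval_too_short")
            return
        t1 = cycle.mdp_time_s + config.eddr_lo * delta
        t2 = cycle.mdp_time_s + config.eddr_hi * delta
    else:
        v = trace.samples
        m0 = cycle._idx["mdp"]
        i_top = int(np.floor(cycle.top_time_s / dt))
        span = cycle.top_mV - cycle.mdp_mV
        t_levels = []
        for frac in (config.eddr_lo, config.eddr_hi):
            level = cycle.mdp_mV + frac * span
            seg = v[m0:i_top + 2]
            hits = np.nonzero((seg[:-1] < level) & (seg[1:] >= level))[0]
            if hits.size == 0:
                cycle.invalidate("no_eddr_voltage_crossing")
                return
            i = int(hits[0]) + m0
            t_levels.append(_interp_crossing(i * dt, dt, v[i], v[i + 1], level))
        t1, t2 = t_levels
        if t2 - t1 < 5 * dt:
            cycle.invalidate("mdp_to_top_interval_too_short")
            return
    cycle.eddr_mV_per_ms = _mean_dvdt_between(dvdt, dt, t1, t2)


def compute_apd50(cycle: APCycle, trace: VoltageTrace) -> None:
    """APD50: time between the half-amplitude crossings of upstroke
    (earliest crossing) and repolarization (first downward crossing after
    the peak), both linearly interpolated."""
    if not cycle.valid:
        return
    v = trace.samples
    dt = trace.sampling_interval
    amp = cycle.amplitude_mV
    if amp <= 0:
        cycle.invalidate("zero_amplitude")
        return
    v50 = cycle.mdp_mV + 0.5 * amp
    m0, pk, m1 = cycle._idx["mdp"], cycle._idx["peak"], cycle._idx["next_mdp"]

    seg = v[m0:pk + 1]
    up = np.nonzero((seg[:-1] < v50) & (seg[1:] >= v50))[0]
    if up.size == 0:
        cycle.invalidate("no_upstroke_crossing")
        return
    i = int(up[0]) + m0
    t_up = _interp_crossing(i * dt, dt, v[i], v[i + 1], v50)

    seg = v[pk:m1 + 1]
    down = np.nonzero((seg[:-1] >= v50) & (seg[1:] < v50))[0]
    if down.size == 0:
        cycle.invalidate("no_repol_crossing")
        return
    j = int(down[0]) + pk
    t_down = _interp_crossing(j * dt, dt, v[j], v[j + 1], v50)
    cycle.apd50_ms = (t_down - t_up) * 1000.0


def summarize_window(cycles: list[APCycle], window: str = "",
                     min_valid_cycles: int = 3) -> APParameters:
    """Mean AP parameters over the valid cycles of a window.

    Firing rate is 60000 / mean cycle length (ms); invalid cycles are
    excluded and counted.  Raises when fewer than ``min_valid_cycles``
    valid cycles remain, naming the window.
    """
    valid = [c for c in cycles if c.valid]
    if len(valid) < min_valid_cycles:
        raise ValueError(
            f"window {window!r}: only {len(valid)} valid cycles "
            f"(need >= {min_valid_cycles})")
    mean = lambda xs: float(np.mean(xs))  # noqa: E731
    mean_cl = mean([c.cycle_length_ms for c in valid])
    return APParameters(
        firing_rate_bpm=60000.0 / mean_cl,
        amplitude_mV=mean([c.amplitude_mV for c in valid]),
        apd50_ms=mean([c.apd50_ms for c in valid]),
        dvdt_max_mV_per_ms=mean([c.dvdt_max_mV_per_ms for c in valid]),
        mdp_mV=mean([c.mdp_mV for c in valid]),
        top_mV=mean([c.top_mV for c in valid]),
        eddr_mV_per_ms=mean([c.eddr_mV_per_ms for c in valid]),
        n_cycles=len(valid), n_invalid=len(cycles) - len(valid),
        window=window,
    )


def extract_cycles(trace: VoltageTrace, config: APConfig = APConfig()
                   ) -> list[APCycle]:
    """Full per-cycle analysis chain: differentiate, detect upstrokes,
    segment, then compute TOP, EDDR and APD50 for every cycle.

    Upstroke landmarks (anchor, dV/dt max, take-off crossing) are measured
    on the noise-robust ``detect_smooth_ms`` derivative; EDDR averages the
    fine ``smoothing_window_ms`` derivative, whose window mean is
    insensitive to white noise.  On noiseless data the two coincide.
    """
    if trace.duration_s < 2.0:
        raise ValueError("need at least 2 s of data")
    dvdt = estimate_dvdt(trace, config)
    dvdt_robust = _savgol_deriv(trace.samples,
                                trace.sampling_interval * 1000.0,
                                config.detect_smooth_ms,
                                config.smoothing_polyorder)
    anchors = detect_aps(trace, dvdt, config)
    if anchors.size < 3:
        return []
    cycles = segment_cycles(trace, dvdt_robust, anchors, config)
    for cyc in cycles:
        compute_top(cyc, trace, dvdt_robust, config)
        compute_eddr(cyc, trace, dvdt, config)
        compute_apd50(cyc, trace)
    return cycles


def cycles_to_frame(cycles: list[APCycle]) -> pd.DataFrame:
    """Per-cycle results as a DataFrame (one row per cycle)."""
    return pd.DataFrame([{
        "mdp_time_s": c.mdp_time_s, "mdp_mV": c.mdp_mV,
        "top_time_s": c.top_time_s, "top_mV": c.top_mV,
        "peak_time_s": c.peak_time_s, "peak_mV": c.peak_mV,
        "next_mdp_time_s": c.next_mdp_time_s,
        "cycle_length_ms": c.cycle_length_ms,
        "rate_bpm": 60000.0 / c.cycle_length_ms,
        "amplitude_mV": c.amplitude_mV,
        "apd50_ms": c.apd50_ms,
        "eddr_mV_per_ms": c.eddr_mV_per_ms,
        "dvdt_max_mV_per_ms": c.dvdt_max_mV_per_ms,
        "valid": c.valid, "invalid_reason": c.invalid_reason,
    } for c in cycles])
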