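"""Drug dose-response analysis for spontaneous firing-rate recordings.

The central statistic is the percent change in firing rate,
``100 * (R_BL - R_drug) / R_BL`` — positive when the drug slows firing.
Baseline/drug/washout rates are window means of the per-cycle rate series;
an optional Hill fit ``E(c) = Emax * c^h / (EC50^h + c^h)`` summarizes the
concentration dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ap_features import APCycle
from .datatypes import RateTimeSeries

__all__ = [
    "WindowConfig",
    "HillFit",
    "rate_series",
    "percent_change",
    "window_rates",
    "classify_washout",
    "fit_hill",
    "build_dose_table",
]


@dataclass(frozen=True)
class WindowConfig:
    """Averaging windows around the perfusion/washout annotations.

    Baseline is the ``baseline_s`` seconds immediately before perfusion;
    the drug window starts ``drug_latency_s`` after perfusion and lasts
    ``drug_duration_s`` (truncated at washout); the washout window starts
    ``washout_latency_s`` after washout.  Defaults: 60 s windows, 60 s
    drug latency.
    """

    baseline_s: float = 60.0
    drug_latency_s: float = 60.0
    drug_duration_s: float = 60.0
    washout_latency_s: float = 120.0
    washout_duration_s: float = 60.0
    washout_tolerance_frac: float = 0.05


@dataclass(frozen=True)
class HillFit:
    """Result of a Hill-equation fit (EC50 in the concentration units of
    the input table; emax in percent change)."""

    ec50: float
    hill_slope: float
    emax: float
    residual_sd: float
    converged: bool
    flag: str = ""


def rate_series(cycles: list[APCycle], events: dict | None = None
                ) -> RateTimeSeries:
    """Per-cycle instantaneous firing rate versus cycle start time, from
    the valid cycles of an AP analysis."""
    valid = [c for c in cycles if c.valid]
    if not valid:
        raise ValueError("no valid cycles to build a rate series from")
    times = np.array([c.mdp_time_s for c in valid])
    rates = np.array([60000.0 / c.cycle_length_ms for c in valid])
    return RateTimeSeries(times_s=times, rates_bpm=rates,
                          events=dict(events or {}))


def percent_change(r_bl: float, r_drug: float) -> float:
    """Percent change in firing rate, ``100 * (r_bl - r_drug) / r_bl``.

    Positive values mean slowing; a speeding drug yields a negative value.
    """
    if r_bl <= 0:
        raise ValueError("baseline rate must be positive")
    return 100.0 * (r_bl - r_drug) / r_bl


def _window_mean(series: RateTimeSeries, t0: float, t1: float,
                 name: str) -> float:
    mask = (series.times_s >= t0) & (series.times_s < t1)
    if not np.any(mask):
        raise ValueError(f"empty {name} window [{t0:.1f}, {t1:.1f}) s")
    return float(np.mean(series.rates_bpm[mask]))


def window_rates(series: RateTimeSeries,
                 config: WindowConfig = WindowConfig()
                 ) -> tuple[float, float, float | None]:
    """Mean rates in the baseline, drug and (if annotated) washout windows.

    Requires a ``perfusion`` event annotation; windows are truncated at the
    next annotation (drug window at washout start).
    """
    if "perfusion" not in series.events:
        raise ValueError("series lacks a 'perfusion' event annotation")
    t_perf = series.events["perfusion"]
    t_wash = series.events.get("washout")

    bl0 = max(t_perf - config.baseline_s, series.times_s[0])
    r_bl = _window_mean(series, bl0, t_perf, "baseline")

    d0 = t_perf + config.drug_latency_s
    d1 = d0 + config.drug_duration_s
    if t_wash is not None:
        d1 = min(d1, t_wash)
    r_drug = _window_mean(series, d0, d1, "drug")

    r_wash = None
    if t_wash is not None:
        w0 = t_wash + config.washout_latency_s
        w1 = min(w0 + config.washout_duration_s, series.times_s[-1] + 1e-9)
        r_wash = _window_mean(series, w0, w1, "washout")
    return r_bl, r_drug, r_wash


def classify_washout(series: RateTimeSeries,
                     config: WindowConfig = WindowConfig()) -> str:
    """Washout classification against baseline rate.

    ``complete`` if the post-washout rate returns to within
    ``washout_tolerance_frac`` (default 5%, boundary inclusive) of
    baseline; ``partial`` if more than half of the drug-induced deficit is
    recovered; ``none`` otherwise.
    """
    if "washout" not in series.events:
        raise ValueError("series lacks a 'washout' event annotation")
    r_bl, r_drug, r_wash = window_rates(series, config)
    if abs(r_wash - r_bl) <= config.washout_tolerance_frac * r_bl:
        return "complete"
    deficit = r_bl - r_drug
    if deficit != 0 and (r_wash - r_drug) / deficit > 0.5:
        return "partial"
    return "none"


def fit_hill(table: pd.DataFrame, response_col: str = "percent_change",
             conc_col: str = "concentration") -> HillFit:
    """Least-squares Hill fit of percent change versus concentration,
    constrained through E(0) = 0.

    Refuses to fit (returns a flagged, non-converged result) when the
    responses are all ~zero or grossly non-monotone in concentration.
    """
    conc = np.asarray(table[conc_col], dtype=float)
    resp = np.asarray(table[response_col], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.unique(conc).size < 4:
        raise ValueError("need >= 4 distinct concentrations")

    if np.max(np.abs(resp)) < 1e-9:
        return HillFit(np.nan, np.nan, 0.0, 0.0, False,
                       flag="all responses zero; fit refused")
    rho = stats.spearmanr(conc, resp).statistic
    if rho < 0:
        return HillFit(np.nan, np.nan, np.nan, np.nan, False,
                       flag="response not increasing with concentration; "
                            "fit refused")

    # fit in log10-concentration space: parameters are then comparably
    # scaled regardless of the molarity range
    logc = np.log10(conc)

    def hill(lc, log_ec50, h, emax):
        return emax / (1.0 + np.power(10.0, h * (log_ec50 - lc)))

    emax0 = float(np.max(resp))
    ec50_0 = float(np.interp(emax0 / 2.0, np.sort(resp),
                             conc[np.argsort(resp)]))
    p0 = [math.log10(max(ec50_0, np.min(conc))), 1.0, emax0]
    try:
        popt, _ = optimize.curve_fit(
            hill, logc, resp, p0=p0,
            bounds=([logc.min() - 3.0, 0.1, -np.inf],
                    [logc.max() + 3.0, 10.0, np.inf]),
            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Hill fit did not converge (starting values log10_ec50="
            f"{p0[0]:.3g}, h={p0[1]}, emax={p0[2]:.3g})") from exc
    resid = resp - hill(logc, *popt)
    return HillFit(ec50=float(10.0 ** popt[0]), hill_slope=float(popt[1]),
                   emax=float(popt[2]),
                   residual_sd=float(np.std(resid)), converged=True)


def build_dose_table(per_cell: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-cell percent changes into a dose-response table.

    ``per_cell`` needs columns ``concentration`` and ``percent_change``
    (one row per cell); returns one row per concentration with the mean,
    SD and n.
    """
    grouped = per_cell.groupby("concentration")["percent_change"]
    out = grouped.agg(percent_change="mean", sd="std", n_cells="count")
    return out.reset_index().sort_values("concentration",
                                         ignore_index=True)
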