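"""Synthetic ground-truth generators for every pipeline stage.

Three generators stand in for raw experimental inputs:

* :func:`generate_ap_train` — spontaneous pacemaker action-potential trains
  built from a piecewise-analytic cycle geometry (linear diastolic ramp,
  logistic upstroke, cosine repolarization).  Because the waveform is
  analytic, the generator returns the *operational* value of every feature
  the extraction stage measures (MDP, take-off potential, EDDR, APD50,
  max dV/dt, cycle length) in closed form, per cycle.
* :func:`generate_rr_series` — beat-interval series with AR(1) variability,
  band-limited sinusoidal modulation, and planted sinus pauses.
* :func:`generate_gene_table` — per-gene replicate expression tables with
  planted group-enriched receptor sets.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .datatypes import RRSeries, VoltageTrace

__all__ = [
    "APGroundTruth",
    "DrugEffectSpec",
    "RRGroundTruth",
    "GeneTableGroundTruth",
    "generate_ap_train",
    "generate_rr_series",
    "generate_gene_table",
]


# ---------------------------------------------------------------------------
# action-potential trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APGroundTruth:
    """Target parameters for one synthetic pacemaker cell.

    The defaults describe a typical adult mouse pacemaker cell: maximum
    diastolic potential near -62 mV, overshoot to +15 mV, take-off around
    -45 mV, early diastolic slope 0.15 mV/ms and a ~333 bpm spontaneous rate.
    """

    mdp_mV: float = -62.0
    peak_mV: float = 15.0
    top_mV: float = -45.0
    edd_slope_mV_per_ms: float = 0.15
    cycle_length_ms: float = 180.0
    apd50_ms: float = 30.0
    upstroke_vmax_mV_per_ms: float = 5.0
    noise_sd_mV: float = 0.2
    drift_mV_per_s: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class DrugEffectSpec:
    """Time course of a perfused agonist acting on the diastolic slope.

    The steady-state effect multiplies the early diastolic slope by
    ``1 - effect_fraction``; onset follows ``1 - exp(-(t - onset)/tau)``.
    An optional washout decays the effect exponentially, and
    ``apd50_stretch_fraction`` lengthens APD50 in proportion to the
    instantaneous activation (mirroring an agonist that slows diastolic
    depolarization and prolongs repolarization without moving MDP/TOP/peak).
    """

    onset_time_s: float = 60.0
    effect_fraction: float = 0.25
    onset_tau_s: float = 20.0
    washout_time_s: float | None = None
    washout_tau_s: float | None = None
    apd50_stretch_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must lie in [0, 1]")
        if self.onset_tau_s <= 0:
            raise ValueError("onset_tau_s must be positive")
        if self.washout_time_s is not None:
            if self.washout_tau_s is None or self.washout_tau_s <= 0:
                raise ValueError("washout requires a positive washout_tau_s")
            if self.washout_time_s <= self.onset_time_s:
                raise ValueError("washout_time_s must follow onset_time_s")
        if self.apd50_stretch_fraction < 0:
            raise ValueError("apd50_stretch_fraction must be >= 0")

    def activation(self, t_s: float) -> float:
        """Normalized activation a(t) in [0, 1]; slope factor = 1 - f*a(t)."""
        if t_s < self.onset_time_s:
            return 0.0
        if self.washout_time_s is None or t_s < self.washout_time_s:
            return 1.0 - math.exp(-(t_s - self.onset_time_s) / self.onset_tau_s)
        a_wo = 1.0 - math.exp(
            -(self.washout_time_s - self.onset_time_s) / self.onset_tau_s
        )
        return a_wo * math.exp(-(t_s - self.washout_time_s) / self.washout_tau_s)


# logistic truncation: the upstroke uses the central (1-2*delta) part of a
# logistic, rescaled to hit TOP and peak exactly at the segment ends
_DELTA = 1e-3


@dataclass(frozen=True)
class CycleGeometry:
    """Closed-form landmark set for one analytic AP cycle (times in ms
    relative to the cycle-start MDP)."""

    mdp: float
    peak: float
    top: float
    slope: float
    cl: float
    apd50: float
    vmax: float
    t_dia: float      # end of diastolic ramp
    t_up: float       # logistic upstroke duration
    t0: float         # logistic midpoint (time of max dV/dt)
    t_pk: float       # time of peak
    t_50up: float     # upstroke half-amplitude crossing
    t_50down: float   # repolarization half-amplitude crossing
    u50: float
    k: float          # logistic steepness (1/ms)
    top_op_mV: float  # operational take-off: V where dV/dt = 10% of max
    top_op_t: float   # its time


def _make_geometry(mdp: float, peak: float, top: float, slope: float,
                   cl: float, apd50: float, vmax: float) -> CycleGeometry:
    """Derive the piecewise cycle geometry, rejecting infeasible parameter
    combinations with a message naming the violated constraint."""
    if not mdp < top < peak:
        raise ValueError("constraint violated: mdp_mV < top_mV < peak_mV")
    for name, val in [("edd_slope_mV_per_ms", slope), ("cycle_length_ms", cl),
                      ("apd50_ms", apd50), ("upstroke_vmax_mV_per_ms", vmax)]:
        if val <= 0:
            raise ValueError(f"constraint violated: {name} must be > 0")
    if 0.1 * vmax <= slope:
        raise ValueError(
            "constraint violated: 10% of upstroke_vmax must exceed "
            "edd_slope (take-off potential otherwise undefined)")

    a_up = peak - top
    t_dia = (top - mdp) / slope
    k = 4.0 * vmax * (1.0 - 2.0 * _DELTA) / a_up
    half_w = math.log((1.0 - _DELTA) / _DELTA) / k
    t_up = 2.0 * half_w
    t0 = t_dia + half_w
    t_pk = t_dia + t_up
    if t_pk >= cl:
        raise ValueError(
            "constraint violated: diastolic interval (top-mdp)/slope plus "
            "upstroke duration exceeds cycle_length_ms")

    v50 = mdp + 0.5 * (peak - mdp)
    sig50 = _DELTA + (v50 - top) * (1.0 - 2.0 * _DELTA) / a_up
    if not 2 * _DELTA < sig50 < 1.0 - 2 * _DELTA:
        raise ValueError(
            "constraint violated: half-amplitude level must fall on the "
            "upstroke (top_mV too close to the mdp/peak midpoint)")
    t_50up = t0 + math.log(sig50 / (1.0 - sig50)) / k
    t_50down = t_50up + apd50
    if t_50down <= t_pk:
        raise ValueError(
            "constraint violated: apd50_ms shorter than the upstroke "
            "peak-to-half interval")
    if t_50down > t_pk + 0.9 * (cl - t_pk):
        raise ValueError(
            "constraint violated: apd50_ms + diastolic interval too long "
            "for cycle_length_ms (no room for terminal repolarization)")
    # keep repolarization slower than twice the upstroke: each cosine
    # half-segment has max slope pi/4 * amplitude / duration
    min_half = math.pi * (peak - mdp) / (8.0 * vmax)
    if t_50down - t_pk < min_half or cl - t_50down < min_half:
        raise ValueError(
            "constraint violated: repolarization steeper than twice the "
            "upstroke vmax (apd50_ms too close to a feasibility edge)")
    u50 = (t_50down - t_pk) / (cl - t_pk)

    # operational take-off point: dV/dt = 4*vmax*sig*(1-sig) on the logistic
    sig_top = 0.5 * (1.0 - math.sqrt(1.0 - 0.1))
    top_op_t = t0 + math.log(sig_top / (1.0 - sig_top)) / k
    top_op_v = top + a_up * (sig_top - _DELTA) / (1.0 - 2.0 * _DELTA)
    if 0.5 * top_op_t >= t_dia:
        raise ValueError(
            "constraint violated: EDDR window (10-50% of MDP-to-TOP "
            "interval) extends past the diastolic ramp")

    return CycleGeometry(mdp=mdp, peak=peak, top=top, slope=slope, cl=cl,
                         apd50=apd50, vmax=vmax, t_dia=t_dia, t_up=t_up,
                         t0=t0, t_pk=t_pk, t_50up=t_50up, t_50down=t_50down,
                         u50=u50, k=k, top_op_mV=top_op_v, top_op_t=top_op_t)


def _eval_cycle(tau_ms: np.ndarray, g: CycleGeometry) -> np.ndarray:
    """Voltage at times ``tau_ms`` (relative to cycle-start MDP)."""
    v = np.empty_like(tau_ms)
    dia = tau_ms < g.t_dia
    v[dia] = g.mdp + g.slope * tau_ms[dia]
    up = (tau_ms >= g.t_dia) & (tau_ms < g.t_pk)
    sig = 1.0 / (1.0 + np.exp(-g.k * (tau_ms[up] - g.t0)))
    v[up] = g.top + (g.peak - g.top) * (sig - _DELTA) / (1.0 - 2.0 * _DELTA)
    rep = tau_ms >= g.t_pk
    u = (tau_ms[rep] - g.t_pk) / (g.cl - g.t_pk)
    phi = np.where(u <= g.u50,
                   u / (2.0 * g.u50),
                   0.5 + (u - g.u50) / (2.0 * (1.0 - g.u50)))
    v[rep] = g.mdp + (g.peak - g.mdp) * 0.5 * (1.0 + np.cos(np.pi * phi))
    return v


def generate_ap_train(gt: APGroundTruth,
                      drug: DrugEffectSpec | None = None,
                      duration_s: float = 30.0,
                      sampling_rate_hz: float = 10_000.0,
                      ) -> tuple[VoltageTrace, pd.DataFrame]:
    """Generate a spontaneous AP train with per-cycle ground truth.

    Each cycle runs MDP-to-MDP: a linear diastolic ramp at the (possibly
    drug-scaled) early diastolic slope, a logistic upstroke with the stated
    maximum dV/dt, and a monotone cosine repolarization whose half-amplitude
    crossing falls exactly ``apd50_ms`` after the upstroke's.  A drug scales
    the slope by ``1 - effect_fraction * a(t)`` (activation frozen at each
    cycle start), lengthening the diastolic interval and hence the cycle.
    White noise and linear drift are added last.

    Returns the trace and a DataFrame with one row per complete cycle:
    start/MDP time, cycle length, rate, MDP, peak, nominal and operational
    TOP, EDDR, APD50 and max dV/dt — the exact values the feature-extraction
    definitions yield on the noiseless waveform.
    """
    if sampling_rate_hz < 5000:
        raise ValueError("sampling_rate_hz must be >= 5000")
    if gt.noise_sd_mV < 0:
        raise ValueError("noise_sd_mV must be >= 0")
    if duration_s * 1000.0 <= 3.0 * gt.cycle_length_ms:
        raise ValueError("duration_s must exceed 3 cycle lengths")

    base = _make_geometry(gt.mdp_mV, gt.peak_mV, gt.top_mV,
                          gt.edd_slope_mV_per_ms, gt.cycle_length_ms,
                          gt.apd50_ms, gt.upstroke_vmax_mV_per_ms)
    t_ap = base.cl - base.t_dia  # AP-complex duration, preserved under drug

    dt_ms = 1000.0 / sampling_rate_hz
    n = int(round(duration_s * sampling_rate_hz))
    v = np.full(n, gt.mdp_mV, dtype=float)

    rows = []
    t_ms = 0.0
    while t_ms < duration_s * 1000.0:
        a = drug.activation(t_ms / 1000.0) if drug is not None else 0.0
        slope_fac = 1.0 - (drug.effect_fraction * a if drug else 0.0)
        apd = gt.apd50_ms * (1.0 + (drug.apd50_stretch_fraction * a if drug else 0.0))
        slope_c = gt.edd_slope_mV_per_ms * slope_fac
        cl_c = base.t_dia / slope_fac + t_ap
        geom = _make_geometry(gt.mdp_mV, gt.peak_mV, gt.top_mV, slope_c,
                              cl_c, apd, gt.upstroke_vmax_mV_per_ms)

        i0 = int(math.ceil(t_ms / dt_ms - 1e-9))
        i1 = min(int(math.ceil((t_ms + cl_c) / dt_ms - 1e-9)), n)
        if i1 > i0:
            tau = np.arange(i0, i1) * dt_ms - t_ms
            v[i0:i1] = _eval_cycle(tau, geom)
        if t_ms + cl_c <= duration_s * 1000.0 + 1e-9:
            rows.append({
                "start_time_s": t_ms / 1000.0,
                "cycle_length_ms": cl_c,
                "rate_bpm": 60000.0 / cl_c,
                "mdp_mV": gt.mdp_mV,
                "peak_mV": gt.peak_mV,
                "top_nominal_mV": gt.top_mV,
                "top_op_mV": geom.top_op_mV,
                "top_op_time_s": (t_ms + geom.top_op_t) / 1000.0,
                "eddr_mV_per_ms": slope_c,
                "apd50_ms": apd,
                "dvdt_max_mV_per_ms": gt.upstroke_vmax_mV_per_ms,
                "amplitude_mV": gt.peak_mV - gt.mdp_mV,
            })
        t_ms += cl_c

    t_s = np.arange(n) / sampling_rate_hz
    if gt.drift_mV_per_s != 0.0:
        v = v + gt.drift_mV_per_s * t_s
    if gt.noise_sd_mV > 0.0:
        rng = np.random.default_rng(gt.seed)
        v = v + rng.normal(0.0, gt.noise_sd_mV, size=n)

    trace = VoltageTrace(sampling_interval=1.0 / sampling_rate_hz, samples=v,
                         metadata={"source": "synthetic", "seed": gt.seed})
    return trace, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RR-interval series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RRGroundTruth:
    """Parameters of a synthetic beat-interval series.

    Defaults emulate murine telemetry: ~600 bpm mean rate, 5 ms beat-to-beat
    SD with mild AR(1) correlation.  ``modulation`` is a list of
    ``(frequency_Hz, amplitude_ms)`` sinusoids; ``pauses`` plants
    ``pause_count`` intervals of ``pause_length_ms``.
    """

    mean_rr_ms: float = 100.0
    sd_rr_ms: float = 5.0
    ar1_coefficient: float = 0.4
    modulation: tuple[tuple[float, float], ...] = ()
    pause_count: int = 0
    pause_length_ms: float = 300.0
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be positive")
        if self.sd_rr_ms < 0:
            raise ValueError("sd_rr_ms must be >= 0")
        if abs(self.ar1_coefficient) >= 1:
            raise ValueError("|ar1_coefficient| must be < 1")
        if self.duration_s * 1000.0 <= 10.0 * self.mean_rr_ms:
            raise ValueError("duration_s must exceed 10 mean RR intervals")


def generate_rr_series(gt: RRGroundTruth) -> RRSeries:
    """Generate RR intervals: mean + stationary AR(1) noise + sinusoidal
    modulation sampled at beat times, with optional planted pauses.

    Raises if the requested variability would push more than 1% of draws to
    non-positive RR; rare residual non-positive values are truncated at 1 ms
    and counted in ``metadata['n_truncated']``.
    """
    sd_tot = math.sqrt(gt.sd_rr_ms ** 2 +
                       sum(a * a / 2.0 for _, a in gt.modulation))
    if sd_tot > 0 and stats.norm.cdf(-gt.mean_rr_ms / sd_tot) > 0.01:
        raise ValueError(
            "infeasible variability: RR <= 0 in more than 1% of draws")

    rng = np.random.default_rng(gt.seed)
    n = int(gt.duration_s * 1000.0 / gt.mean_rr_ms * 1.2) + 20
    burn = 200
    phi = gt.ar1_coefficient
    eps = rng.normal(0.0, gt.sd_rr_ms * math.sqrt(1.0 - phi * phi), n + burn)
    x = signal.lfilter([1.0], [1.0, -phi], eps)[burn:]

    rr = gt.mean_rr_ms + x
    if gt.modulation:
        t_approx = np.cumsum(rr) / 1000.0  # first-pass beat times
        for f_hz, amp in gt.modulation:
            rr = rr + amp * np.sin(2.0 * np.pi * f_hz * t_approx)

    n_trunc = int(np.sum(rr <= 0))
    rr = np.maximum(rr, 1.0)

    if gt.pause_count > 0:
        # plant only among beats that survive the duration trim (pauses
        # themselves consume recording time)
        usable = int((gt.duration_s * 1000.0 -
                      gt.pause_count * gt.pause_length_ms) / gt.mean_rr_ms)
        usable = min(usable - 5, n - 5)
        if gt.pause_count > usable - 5:
            raise ValueError("pause_count exceeds available beats")
        pos = rng.choice(np.arange(5, usable), size=gt.pause_count,
                         replace=False)
        rr[pos] = gt.pause_length_ms

    beat_times = np.cumsum(rr) / 1000.0
    keep = beat_times <= gt.duration_s
    return RRSeries(beat_times_s=beat_times[keep], rr_ms=rr[keep],
                    metadata={"source": "synthetic", "seed": gt.seed,
                              "n_truncated": n_trunc})


# ---------------------------------------------------------------------------
# gene-expression replicate tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneTableGroundTruth:
    """Planted-truth design for a two-group receptor expression table.

    Defaults mirror the structure of a sorted-cell comparison between
    sinoatrial-node pacemaker cells (group A) and right-atrial
    cardiomyocytes (group B): 71 expressed receptors of which 13 are
    A-enriched, 18 B-enriched and 40 shared, 3 replicates per group.
    """

    n_genes: int = 2000
    n_receptors: int = 71
    n_enriched_a: int = 13
    n_enriched_b: int = 18
    n_replicates: int = 3
    log2_fc: float = 4.0
    dispersion: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group")
        if self.n_enriched_a + self.n_enriched_b > self.n_receptors:
            raise ValueError("planted sets exceed receptor count")
        if self.n_receptors > self.n_genes:
            raise ValueError("n_receptors exceeds n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def generate_gene_table(gt: GeneTableGroundTruth,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Generate per-gene replicate expression values with planted effects.

    Per-gene baselines are drawn log-uniformly (log2 mean in [3, 10]) and
    replicates are log-normal around them; planted genes are shifted by
    ``log2_fc`` in their enriched group.  Returns ``(values, truth,
    receptor_ids)`` where ``values`` is genes x samples on the linear scale
    (columns ``A_1..A_r, B_1..B_r``) and ``truth`` carries the planted class
    per gene (``enriched_A``/``enriched_B``/``shared``/``non_receptor``).
    """
    rng = np.random.default_rng(gt.seed)
    n_rec = gt.n_receptors
    receptor_ids = [f"Gpr{i:04d}" for i in range(n_rec)]
    other_ids = [f"Gene{i:04d}" for i in range(gt.n_genes - n_rec)]
    genes = receptor_ids + other_ids

    classes = np.array(["non_receptor"] * gt.n_genes, dtype=object)
    planted = rng.permutation(n_rec)
    idx_a = planted[:gt.n_enriched_a]
    idx_b = planted[gt.n_enriched_a:gt.n_enriched_a + gt.n_enriched_b]
    classes[:n_rec] = "shared"
    classes[idx_a] = "enriched_A"
    classes[idx_b] = "enriched_B"

    base = rng.uniform(3.0, 10.0, size=gt.n_genes)
    mean_a = base.copy()
    mean_b = base.copy()
    mean_a[idx_a] += gt.log2_fc
    mean_b[idx_b] += gt.log2_fc

    r = gt.n_replicates
    log2_a = mean_a[:, None] + rng.normal(0.0, gt.dispersion, (gt.n_genes, r))
    log2_b = mean_b[:, None] + rng.normal(0.0, gt.dispersion, (gt.n_genes, r))
    values = pd.DataFrame(
        np.power(2.0, np.hstack([log2_a, log2_b])),
        index=pd.Index(genes, name="gene_id"),
        columns=[f"A_{i+1}" for i in range(r)] + [f"B_{i+1}" for i in range(r)],
    )
    truth = pd.DataFrame({"gene_id": genes, "true_class": classes}
                         ).set_index("gene_id")
    return values, truth, receptor_ids
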