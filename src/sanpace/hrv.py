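"""Telemetry heart-rhythm analysis on RR-interval series.

Time-domain variability (RMSSD, SDRR, pNNx), frequency-domain band powers
of the RR tachogram (Lomb-Scargle on the unevenly sampled beats by
default, or cubic interpolation + Welch), 10-bpm heart-rate histograms per
activity period, and RR-based counting of sinus pauses and bradycardia
episodes.

Murine LF/HF band defaults (LF 0.15-1.5 Hz, HF 1.5-5 Hz) follow common
telemetry convention and are always echoed in the result object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from .datatypes import RRSeries

__all__ = [
    "SpectralBands",
    "EpisodeConfig",
    "HRVResult",
    "Episode",
    "EpisodeReport",
    "time_domain",
    "frequency_domain",
    "rate_histogram",
    "detect_episodes",
]


@dataclass(frozen=True)
class SpectralBands:
    """LF/HF band edges in Hz (defaults for mouse telemetry)."""

    lf_lo: float = 0.15
    lf_hi: float = 1.5
    hf_lo: float = 1.5
    hf_hi: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.lf_lo < self.lf_hi <= self.hf_lo < self.hf_hi:
            raise ValueError("bands must satisfy lf_lo < lf_hi <= hf_lo < hf_hi")


@dataclass(frozen=True)
class EpisodeConfig:
    """Thresholds for pause/bradycardia detection (echoed in reports).

    A sinus pause is an RR exceeding ``pause_factor`` times the rolling
    median RR (window ``median_window_beats``); a bradycardia episode is
    ``min_consecutive_beats`` or more consecutive beats below
    ``brady_bpm``.  Episodes separated by fewer than ``merge_gap_beats``
    beats are merged.
    """

    pause_factor: float = 2.0
    median_window_beats: int = 50
    brady_bpm: float = 400.0
    min_consecutive_beats: int = 10
    merge_gap_beats: int = 5


@dataclass(frozen=True)
class HRVResult:
    """Time- and/or frequency-domain HRV summary for one window."""

    n_beats: int
    window: str = ""
    rmssd_ms: float = np.nan
    sdrr_ms: float = np.nan
    pnnx_percent: float = np.nan
    pnnx_threshold_ms: float = np.nan
    total_power_ms2: float = np.nan
    lf_power_ms2: float = np.nan
    hf_power_ms2: float = np.nan
    bands: SpectralBands | None = None
    method: str = ""


@dataclass(frozen=True)
class Episode:
    start_time_s: float
    end_time_s: float
    n_beats: int


@dataclass(frozen=True)
class EpisodeReport:
    """Counts and time-stamped lists of detected rhythm events."""

    pauses: list[Episode] = field(default_factory=list)
    bradycardia: list[Episode] = field(default_factory=list)
    config: EpisodeConfig = EpisodeConfig()

    @property
    def n_pauses(self) -> int:
        return len(self.pauses)

    @property
    def n_bradycardia(self) -> int:
        return len(self.bradycardia)


# ---------------------------------------------------------------------------

def time_domain(rr: RRSeries, pnnx_threshold_ms: float = 6.0,
                window: str = "") -> HRVResult:
    """Time-domain HRV: RMSSD, SDRR (n-1 sample SD) and pNNx.

    pNNx is the percentage of successive-RR differences of at least
    ``pnnx_threshold_ms`` in magnitude (inclusive; the conventional
    murine threshold is 6 ms).
    """
    x = rr.rr_ms
    if x.size < 2:
        raise ValueError("need at least 2 RR intervals")
    d = np.diff(x)
    return HRVResult(
        n_beats=x.size, window=window,
        rmssd_ms=float(np.sqrt(np.mean(d * d))),
        sdrr_ms=float(np.std(x, ddof=1)),
        pnnx_percent=float(100.0 * np.mean(np.abs(d) >= pnnx_threshold_ms)),
        pnnx_threshold_ms=pnnx_threshold_ms,
    )


def _lomb_scargle_psd(t_s: np.ndarray, y: np.ndarray, f_max: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD estimate (ms^2/Hz) of an unevenly sampled series via
    the Lomb-Scargle periodogram, scaled so band integrals approximate the
    series variance."""
    span = t_s[-1] - t_s[0]
    f_min = 1.0 / span
    freqs = np.arange(f_min, f_max, f_min / 4.0)  # 4x oversampled grid
    p = signal.lombscargle(t_s, y - np.mean(y), 2.0 * np.pi * freqs)
    fs_eff = t_s.size / span  # mean beat rate
    psd = 2.0 * p / fs_eff
    return freqs, psd


def frequency_domain(rr: RRSeries, bands: SpectralBands = SpectralBands(),
                     method: str = "lomb-scargle",
                     resample_hz: float = 20.0,
                     window: str = "") -> HRVResult:
    """Band powers of the RR tachogram.

    ``lomb-scargle`` (default) evaluates the periodogram of the unevenly
    sampled intervals directly; ``welch`` cubic-interpolates the tachogram
    onto a uniform ``resample_hz`` grid first.  Band powers (ms^2) are
    trapezoidal integrals of the PSD over the configured LF/HF bands;
    total power integrates the full estimated spectrum up to ``hf_hi``, so
    lf + hf <= total by construction.
    """
    if rr.duration_s < 60.0:
        raise ValueError("need a window of at least 60 s of beats")
    t, y = rr.beat_times_s, rr.rr_ms
    if method == "lomb-scargle":
        freqs, psd = _lomb_scargle_psd(t, y, bands.hf_hi)
    elif method == "welch":
        grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
        yy = interpolate.CubicSpline(t, y)(grid)
        nper = min(yy.size, int(resample_hz * 60))
        freqs, psd = signal.welch(yy - np.mean(yy), fs=resample_hz,
                                  nperseg=nper)
        keep = freqs <= bands.hf_hi
        freqs, psd = freqs[keep], psd[keep]
    else:
        raise ValueError("method must be 'lomb-scargle' or 'welch'")

    def band_power(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))

    return HRVResult(
        n_beats=y.size, window=window,
        total_power_ms2=band_power(freqs[0], bands.hf_hi),
        lf_power_ms2=band_power(bands.lf_lo, bands.lf_hi),
        hf_power_ms2=band_power(bands.hf_lo, bands.hf_hi),
        bands=bands, method=method,
    )


def rate_histogram(rr: RRSeries, bin_bpm: float = 10.0,
                   period_labels: np.ndarray | None = None) -> pd.DataFrame:
    """Instantaneous heart-rate histogram in ``bin_bpm``-wide half-open
    bins ``[k*bin, (k+1)*bin)``, normalized to fractions per activity
    period.

    Returns a tidy frame with columns ``period``, ``bin_lo_bpm``,
    ``bin_hi_bpm`` and ``fraction``; fractions sum to 1 within each period.
    """
    hr = rr.heart_rate_bpm
    labels = period_labels if period_labels is not None else rr.period_labels
    if labels is None:
        labels = np.array(["all"] * rr.n_beats)
    labels = np.asarray(labels)
    if labels.shape != hr.shape:
        raise ValueError("period labels must cover every beat")

    rows = []
    for period in pd.unique(labels):
        h = hr[labels == period]
        k = np.floor(h / bin_bpm).astype(int)
        counts = pd.Series(k).value_counts().sort_index()
        frac = counts / counts.sum()
        for kk, f in frac.items():
            rows.append({"period": period, "bin_lo_bpm": kk * bin_bpm,
                         "bin_hi_bpm": (kk + 1) * bin_bpm,
                         "fraction": float(f)})
    return pd.DataFrame(rows)


def _merge_runs(idx: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Group flagged beat indices into runs, merging runs separated by
    fewer than ``merge_gap`` beats; returns (start, end) inclusive."""
    if idx.size == 0:
        return []
    runs = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i - prev < merge_gap:
            prev = int(i)
        else:
            runs.append((start, prev))
            start = prev = int(i)
    runs.append((start, prev))
    return runs


def detect_episodes(rr: RRSeries, config: EpisodeConfig = EpisodeConfig()
                    ) -> EpisodeReport:
    """Count sinus pauses and bradycardia episodes from RR alone.

    Pause and bradycardia thresholds are relative/absolute as configured;
    rolling-median normalization makes pause detection robust to slow rate
    drift.  (AV block is not detectable from RR series and is not
    attempted.)
    """
    x = rr.rr_ms
    t = rr.beat_times_s
    rolmed = pd.Series(x).rolling(config.median_window_beats, center=True,
                                  min_periods=1).median().to_numpy()
    pause_idx = np.nonzero(x > config.pause_factor * rolmed)[0]
    pauses = [Episode(start_time_s=float(t[a] - x[a] / 1000.0),
                      end_time_s=float(t[b]), n_beats=b - a + 1)
              for a, b in _merge_runs(pause_idx, config.merge_gap_beats)]

    slow = np.nonzero(60000.0 / x < config.brady_bpm)[0]
    brady = [Episode(start_time_s=float(t[a] - x[a] / 1000.0),
                     end_time_s=float(t[b]), n_beats=b - a + 1)
             for a, b in _merge_runs(slow, config.merge_gap_beats)
             if b - a + 1 >= config.min_consecutive_beats]
    return EpisodeReport(pauses=pauses, bradycardia=brady, config=config)
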