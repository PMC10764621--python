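"""Shared containers for traces, beat series, and analysis results.

Conventions used throughout the package:

* membrane potential in millivolts, time in seconds, dV/dt in mV/ms;
* RR intervals in milliseconds, beat times in seconds;
* firing rates and heart rates in beats per minute (bpm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane-potential recording.

    Parameters
    ----------
    sampling_interval
        Time between samples, in seconds.
    samples
        Membrane potential at each sample, in mV.
    metadata
        Free-form annotations (cell id, condition label, source file).
    """

    sampling_interval: float
    samples: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values; clean on read")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) * self.sampling_interval


@dataclass
class RRSeries:
    """Beat-interval series: beat times (s) and the RR interval (ms) ending
    at each beat. Optional per-beat activity annotation and period labels
    (e.g. ``low``/``high`` activity) for windowed telemetry analysis."""

    beat_times_s: np.ndarray
    rr_ms: np.ndarray
    activity: np.ndarray | None = None
    period_labels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.beat_times_s.shape != self.rr_ms.shape:
            raise ValueError("beat_times_s and rr_ms must have equal length")
        if np.any(self.rr_ms <= 0):
            raise ValueError("all RR intervals must be positive")
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.period_labels is not None:
            self.period_labels = np.asarray(self.period_labels)
            if self.period_labels.shape != self.rr_ms.shape:
                raise ValueError("period_labels must match beat count")

    @property
    def n_beats(self) -> int:
        return self.rr_ms.size

    @property
    def duration_s(self) -> float:
        return float(self.beat_times_s[-1] - self.beat_times_s[0])

    @property
    def heart_rate_bpm(self) -> np.ndarray:
        """Instantaneous heart rate per beat, 60000 / RR(ms)."""
        return 60000.0 / self.rr_ms


@dataclass
class RateTimeSeries:
    """Per-cycle instantaneous firing rate (bpm) versus time with event
    annotations (perfusion start, washout start) used by the dose-response
    windowing."""

    times_s: np.ndarray
    rates_bpm: np.ndarray
    events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.rates_bpm = np.asarray(self.rates_bpm, dtype=float)
        if self.times_s.shape != self.rates_bpm.shape:
            raise ValueError("times and rates must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, t in self.events.items():
            if not (self.times_s[0] <= t <= self.times_s[-1]):
                raise ValueError(
                    f"event {name!r} at {t} s lies outside the recording span"
                )
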