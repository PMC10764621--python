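"""Umbrella pipeline binding the analysis stages.

Stage order is fixed: synthetic generation first, then AP feature
extraction, then the downstream dose/HRV/gene analyses.  All randomness
flows from the seeds in the configuration; outputs are plain CSV/JSON and
are byte-identical across reruns of the same config + seed.  On a stage
failure the partial outputs are kept and the MANIFEST records which stage
failed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__, ap_features, dose_response, expression, hrv, io, \
    synth
from .config import RunConfig

__all__ = ["run_pipeline"]

log = logging.getLogger("sanpace")

_STAGE_ORDER = ("synth_ap", "synth_rr", "synth_genes", "ap", "dose",
                "hrv", "genes")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _reseed(base, seed: int):
    """Return a copy of a frozen ground-truth spec with its seed replaced."""
    return dataclasses.replace(base, seed=seed)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None
                 ) -> dict:
    """Execute the configured stages and write the output bundle.

    Returns the machine-readable report (also written as ``report.json``);
    the MANIFEST echoes the full configuration, package version and
    per-stage status.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    manifest = {"package": "sanpace", "version": __version__,
                "config_hash": _config_hash(config),
                "config": config.to_dict(), "stages": {}, "failed": None}
    state: dict = {}

    stages = [s for s in _STAGE_ORDER if s in config.stages]
    try:
        for stage in stages:
            t0 = time.perf_counter()
            _run_stage(stage, config, out, state, report)
            log.info("stage %s finished in %.2f s (seed %d)", stage,
                     time.perf_counter() - t0, config.seed)
            manifest["stages"][stage] = "ok"
    except Exception:
        manifest["stages"][stage] = "failed"
        manifest["failed"] = stage
        (out / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n")
        raise
    (out / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=str) + "\n")
    return report


def _run_stage(stage: str, config: RunConfig, out: Path, state: dict,
               report: dict) -> None:
    if stage == "synth_ap":
        gt = _reseed(config.synth_ap, config.seed)
        trace, truth = synth.generate_ap_train(
            gt, config.synth_drug, duration_s=config.duration_s,
            sampling_rate_hz=config.sampling_rate_hz)
        io.write_trace(trace, out / "trace.csv")
        truth.to_csv(out / "trace_truth.csv", index=False,
                     float_format="%.9g")
        state["trace"], state["trace_truth"] = trace, truth
        report["stages"]["synth_ap"] = {"n_samples": trace.n_samples,
                                        "n_cycles_truth": len(truth)}

    elif stage == "synth_rr":
        gt = _reseed(config.synth_rr, config.seed + 1)
        rr = synth.generate_rr_series(gt)
        io.write_rr(rr, out / "rr.csv")
        state["rr"] = rr
        report["stages"]["synth_rr"] = {"n_beats": rr.n_beats}

    elif stage == "synth_genes":
        gt = _reseed(config.synth_genes, config.seed + 2)
        values, truth, receptors = synth.generate_gene_table(gt)
        values.to_csv(out / "gene_values.csv", float_format="%.9g")
        truth.to_csv(out / "gene_truth.csv")
        (out / "receptors.txt").write_text("\n".join(receptors) + "\n")
        state["gene_values"], state["receptors"] = values, receptors
        report["stages"]["synth_genes"] = {"n_genes": len(values)}

    elif stage == "ap":
        trace = state.get("trace") or io.read_trace(out / "trace.csv")
        cycles = ap_features.extract_cycles(trace, config.ap)
        frame = ap_features.cycles_to_frame(cycles)
        frame.to_csv(out / "cycles.csv", index=False, float_format="%.9g")
        summary = ap_features.summarize_window(
            cycles, window="all", min_valid_cycles=config.ap.min_valid_cycles)
        report["stages"]["ap"] = dataclasses.asdict(summary)
        state["cycles"] = cycles
        pd.DataFrame([dataclasses.asdict(summary)]).to_csv(
            out / "ap_summary.csv", index=False, float_format="%.9g")

    elif stage == "dose":
        cycles = state.get("cycles")
        if cycles is None:
            raise ValueError("dose stage requires the ap stage")
        drug = config.synth_drug
        if drug is None:
            raise ValueError("dose stage requires a synth_drug section "
                             "(perfusion annotations)")
        events = {"perfusion": drug.onset_time_s}
        if drug.washout_time_s is not None:
            events["washout"] = drug.washout_time_s
        series = dose_response.rate_series(cycles, events)
        r_bl, r_drug, r_wash = dose_response.window_rates(series, config.dose)
        entry = {"r_baseline_bpm": r_bl, "r_drug_bpm": r_drug,
                 "percent_change": dose_response.percent_change(r_bl, r_drug),
                 "concentration": config.concentration}
        if r_wash is not None:
            entry["r_washout_bpm"] = r_wash
            entry["washout_class"] = dose_response.classify_washout(
                series, config.dose)
        report["stages"]["dose"] = entry
        pd.DataFrame([entry]).to_csv(out / "dose.csv", index=False,
                                     float_format="%.9g")

    elif stage == "hrv":
        rr = state.get("rr") or io.read_rr(out / "rr.csv")
        td = hrv.time_domain(rr)
        fd = hrv.frequency_domain(rr, config.bands)
        episodes = hrv.detect_episodes(rr, config.episodes)
        hist = hrv.rate_histogram(rr)
        hist.to_csv(out / "rate_histogram.csv", index=False,
                    float_format="%.9g")
        entry = {
            "rmssd_ms": td.rmssd_ms, "sdrr_ms": td.sdrr_ms,
            "pnnx_percent": td.pnnx_percent,
            "pnnx_threshold_ms": td.pnnx_threshold_ms,
            "total_power_ms2": fd.total_power_ms2,
            "lf_power_ms2": fd.lf_power_ms2,
            "hf_power_ms2": fd.hf_power_ms2,
            "bands_hz": dataclasses.asdict(config.bands),
            "n_pauses": episodes.n_pauses,
            "n_bradycardia": episodes.n_bradycardia,
            "episode_thresholds": dataclasses.asdict(config.episodes),
        }
        report["stages"]["hrv"] = entry
        (out / "hrv.json").write_text(json.dumps(entry, indent=2) + "\n")

    elif stage == "genes":
        values = state.get("gene_values")
        receptors = state.get("receptors")
        if values is None:
            values = pd.read_csv(out / "gene_values.csv",
                                 index_col="gene_id")
            receptors = io.read_receptor_list(out / "receptors.txt")
        stats_table = expression.differential_stats(values)
        counts, labeled = expression.classify_receptors(
            stats_table, receptors, fdr=config.fdr)
        labeled.to_csv(out / "receptor_classes.csv", float_format="%.9g")
        entry = dataclasses.asdict(counts) | {"fdr": config.fdr}
        report["stages"]["genes"] = entry
        (out / "receptor_counts.json").write_text(
            json.dumps(entry, indent=2) + "\n")

    else:  # pragma: no cover - guarded by RunConfig validation
        raise ValueError(f"unknown stage {stage!r}")
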