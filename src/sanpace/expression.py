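"""Receptor catalog classification and relative qPCR quantification.

Workflow for the GPCR catalog: per-gene two-group statistics on
log-transformed replicate values, Benjamini-Hochberg FDR adjustment, then
intersection with an annotated receptor list and partition into
group-A-enriched / group-B-enriched / shared classes at a chosen FDR.
Externally computed (log2 fold change, p) tables can be slotted in
directly, so published differential-expression outputs work unchanged.

qPCR quantification uses the comparative-CT (delta-delta-CT) method with an
endogenous control gene; fold change = 2^(-ddCT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PartitionCounts",
    "bh_adjust",
    "differential_stats",
    "classify_receptors",
    "ddct",
    "zscore_matrix",
]


@dataclass(frozen=True)
class PartitionCounts:
    """Receptor partition sizes; n_a + n_b + n_shared == n_total."""

    n_total: int
    n_a: int
    n_b: int
    n_shared: int


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    For sorted p-values p_(1) <= ... <= p_(m),
    ``q_(k) = min_{i >= k} min(m * p_(i) / i, 1)``; ties are handled
    stably and the output is returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def differential_stats(values: pd.DataFrame,
                       group_a: list[str] | None = None,
                       group_b: list[str] | None = None,
                       log_base: float = 2.0) -> pd.DataFrame:
    """Per-gene two-group comparison on log-transformed expression.

    ``values`` is genes x samples on the linear scale; columns prefixed
    ``A_``/``B_`` define the groups unless given explicitly.  Returns a
    per-gene table with group means (log2), ``lfc`` (mean A - mean B,
    log2), a pooled-variance two-sample t ``p_value`` and BH ``q_value``
    over all genes in the table.  The pooled test keeps stable degrees of
    freedom at the small replicate counts typical of sorted-cell designs.
    Genes with zero variance and zero difference get p = 1 by convention.
    """
    if group_a is None:
        group_a = [c for c in values.columns if str(c).startswith("A_")]
    if group_b is None:
        group_b = [c for c in values.columns if str(c).startswith("B_")]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")

    log_a = np.log2(values[group_a].to_numpy(dtype=float))
    log_b = np.log2(values[group_b].to_numpy(dtype=float))
    mean_a, mean_b = log_a.mean(axis=1), log_b.mean(axis=1)
    lfc = mean_a - mean_b

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=True)
    degenerate = (log_a.var(axis=1) == 0) & (log_b.var(axis=1) == 0)
    p = np.where(degenerate & (lfc == 0), 1.0, p)
    p = np.where(degenerate & (lfc != 0), 0.0, p)

    return pd.DataFrame({
        "mean_a_log2": mean_a, "mean_b_log2": mean_b,
        "lfc": lfc, "p_value": p, "q_value": bh_adjust(p),
    }, index=values.index)


def classify_receptors(table: pd.DataFrame, receptor_ids: list[str],
                       fdr: float = 0.05,
                       expression_floor_log2: float = 1.0,
                       ) -> tuple[PartitionCounts, pd.DataFrame]:
    """Partition the expressed receptors by differential expression.

    Restricts ``table`` (per-gene stats with ``mean_a_log2``,
    ``mean_b_log2``, ``lfc``, ``q_value``) to ``receptor_ids`` whose mean
    expression clears ``expression_floor_log2`` in at least one group,
    then labels each receptor ``enriched_A`` (q < fdr, lfc > 0),
    ``enriched_B`` (q < fdr, lfc < 0) or ``shared``.  Returns the counts
    and the labeled table; the thresholds used are attached to the table's
    ``attrs``.
    """
    present = table.index.intersection(pd.Index(receptor_ids))
    if present.empty:
        raise ValueError("no receptor ids found in the statistics table")
    sub = table.loc[present].copy()
    expressed = (sub["mean_a_log2"] >= expression_floor_log2) | \
                (sub["mean_b_log2"] >= expression_floor_log2)
    sub = sub[expressed]
    if sub.empty:
        raise ValueError("no receptors above the expression floor")

    sig = sub["q_value"] < fdr
    label = np.where(sig & (sub["lfc"] > 0), "enriched_A",
                     np.where(sig & (sub["lfc"] < 0), "enriched_B",
                              "shared"))
    sub["class"] = label
    counts = PartitionCounts(
        n_total=len(sub),
        n_a=int((label == "enriched_A").sum()),
        n_b=int((label == "enriched_B").sum()),
        n_shared=int((label == "shared").sum()),
    )
    sub.attrs.update({"fdr": fdr,
                      "expression_floor_log2": expression_floor_log2})
    return counts, sub


def ddct(ct: pd.DataFrame, calibrator_group: str,
         undetected_ct: float = 40.0) -> pd.DataFrame:
    """Comparative-CT quantification relative to a calibrator group.

    ``ct`` needs columns ``group``, ``target_ct`` and ``control_ct`` (one
    row per sample).  Per sample dCT = target - control; per group
    ddCT = mean dCT(group) - mean dCT(calibrator); fold = 2^(-ddCT).

    Missing target CTs (undetected transcript, as when a gene is absent
    from one tissue) are censored at ``undetected_ct`` cycles and the
    group's fold change is flagged as an upper bound.  Missing control CTs
    are an error.
    """
    required = {"group", "target_ct", "control_ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"CT table must have columns {sorted(required)}")
    if ct["control_ct"].isna().any():
        raise ValueError("missing endogenous-control CT values")
    if calibrator_group not in set(ct["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent")

    work = ct.copy()
    censored_groups = set(work.loc[work["target_ct"].isna(), "group"])
    work["target_ct"] = work["target_ct"].fillna(undetected_ct)
    bad = (work[["target_ct", "control_ct"]] <= 0) | \
          (work[["target_ct", "control_ct"]] >= 45)
    if bad.to_numpy().any():
        raise ValueError("CT values must lie in (0, 45)")
    work["dct"] = work["target_ct"] - work["control_ct"]

    per_group = work.groupby("group")["dct"].agg(["mean", "std", "count"])
    cal = per_group.loc[calibrator_group, "mean"]
    out = per_group.rename(columns={"mean": "dct_mean", "std": "dct_sd",
                                    "count": "n"})
    out["ddct"] = out["dct_mean"] - cal
    out["fold_change"] = np.power(2.0, -out["ddct"])
    out["censored_upper_bound"] = [g in censored_groups for g in out.index]
    return out.reset_index()


def zscore_matrix(values: pd.DataFrame, log: bool = True) -> pd.DataFrame:
    """Per-gene z-scored (log2) expression matrix for heatmap rendering."""
    x = np.log2(values.to_numpy(dtype=float)) if log else \
        values.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((x - mu) / sd, index=values.index,
                        columns=values.columns)
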