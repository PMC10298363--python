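"""Transcript usage, expression filtering, and differential transcript usage.

Transcript usage (isoform fraction) is a transcript's TPM divided by the
summed TPM of all transcripts of its parent gene within one sample; samples
where the gene is unexpressed get usage exactly 0. The mean change in usage
(dIF) is the mean usage in cancer samples minus the mean usage in normal
samples. The built-in DTU test compares per-sample usage values between
conditions with a two-sided rank-sum test; externally produced DTU tables
(e.g. from quasi-binomial frameworks) can be loaded instead and flow
through the identical downstream machinery. Multiple-testing correction is
Benjamini-Hochberg applied globally over all cohorts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import CONDITIONS, ExpressionMatrix
from .stats import adjust_global, rank_sum_test_rows

DTU_COLUMNS = [
    "transcript_id", "gene_id", "cohort", "mean_usage_normal",
    "mean_usage_cancer", "dIF", "p", "adj_p", "usage_direction",
]


def compute_usage(tpm: ExpressionMatrix, annotation: pd.Series) -> pd.DataFrame:
    """Per-sample transcript usage: TPM over parent-gene TPM, 0 where the gene is off."""
    if tpm.kind != "tpm":
        raise ValueError("usage must be computed from a TPM matrix")
    genes = annotation.reindex(tpm.values.index)
    if genes.isna().any():
        missing = tpm.values.index[genes.isna().to_numpy()][0]
        raise ValueError(f"transcript {missing!r} missing from annotation")
    gene_sums = tpm.values.groupby(genes.to_numpy()).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = tpm.values / gene_sums
    usage = usage.where(gene_sums > 0, 0.0)
    return usage


def _cohort_groups(
    samples: pd.DataFrame, cohort: str
) -> tuple[list[str], list[str]]:
    sub = samples[samples["cohort"] == cohort]
    if len(sub) == 0:
        raise ValueError(f"unknown cohort {cohort!r}")
    groups = {}
    for cond in CONDITIONS:
        ids = list(sub.index[sub["condition"] == cond])
        if not ids:
            raise ValueError(f"cohort {cohort!r} has no {cond} samples")
        groups[cond] = ids
    return groups["normal"], groups["cancer"]


def mean_usage_change(
    usage: pd.DataFrame, samples: pd.DataFrame, cohort: str
) -> pd.DataFrame:
    """Condition-wise mean usages and their difference (dIF) per transcript."""
    normal_ids, cancer_ids = _cohort_groups(samples, cohort)
    mean_normal = usage[normal_ids].mean(axis=1)
    mean_cancer = usage[cancer_ids].mean(axis=1)
    return pd.DataFrame(
        {
            "mean_usage_normal": mean_normal,
            "mean_usage_cancer": mean_cancer,
            "dIF": mean_cancer - mean_normal,
        }
    )


def filter_transcripts(
    counts: ExpressionMatrix,
    samples: pd.DataFrame,
    cohort: str,
    min_count: float = 10,
    min_total: float = 15,
    large_n: int = 10,
    min_prop: float = 0.7,
) -> set[str]:
    """Expression filter on counts ahead of both the DTU and the DTE tests.

    Reimplements the documented default logic of the standard count filter
    used by differential-expression workflows: a transcript is kept when its
    CPM reaches ``min_count`` scaled by the median library size (in
    millions) in at least ``n_min`` samples, and its total count across the
    cohort's samples reaches ``min_total``. ``n_min`` is the smaller
    condition group's size, attenuated for large groups: beyond ``large_n``
    samples only a ``min_prop`` fraction of the excess is required
    (``n_min = large_n + min_prop * (min_group - large_n)``).
    ``min_count = 0`` with ``min_total = 0`` keeps everything.
    """
    if counts.kind != "counts":
        raise ValueError("the expression filter operates on raw counts")
    normal_ids, cancer_ids = _cohort_groups(samples, cohort)
    ids = normal_ids + cancer_ids
    sub = counts.values[ids]
    lib_sizes = sub.sum(axis=0)
    median_millions = float(np.median(lib_sizes)) / 1e6
    if median_millions <= 0:
        raise ValueError(f"cohort {cohort!r} has zero median library size")
    cpm_cutoff = min_count / median_millions
    with np.errstate(invalid="ignore", divide="ignore"):
        cpm = sub / lib_sizes * 1e6
    cpm = cpm.fillna(0.0)
    n_min = min(len(normal_ids), len(cancer_ids))
    if n_min > large_n:
        n_min = large_n + min_prop * (n_min - large_n)
    tol = 1e-14
    enough_samples = (cpm >= cpm_cutoff).sum(axis=1) >= n_min - tol
    enough_total = sub.sum(axis=1) >= min_total - tol
    kept = set(sub.index[(enough_samples & enough_total).to_numpy()])
    if not kept:
        raise ValueError(
            f"expression filter removed every transcript in cohort {cohort!r}; "
            "lower min_count/min_total"
        )
    return kept


def test_dtu(
    usage: pd.DataFrame,
    samples: pd.DataFrame,
    cohort: str,
    kept: set[str] | None = None,
) -> pd.Series:
    """Two-sided rank-sum p-values on per-sample usage, per kept transcript."""
    normal_ids, cancer_ids = _cohort_groups(samples, cohort)
    if kept is None:
        index = usage.index
    else:
        index = usage.index[usage.index.isin(kept)]
    X = usage.loc[index, cancer_ids].to_numpy()
    Y = usage.loc[index, normal_ids].to_numpy()
    p = rank_sum_test_rows(X, Y)
    return pd.Series(p, index=index, name="p")


def run_dtu(
    usage: pd.DataFrame,
    annotation: pd.Series,
    samples: pd.DataFrame,
    kept_per_cohort: dict[str, set[str]] | None,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Full DTU table over all cohorts with global BH adjustment.

    p-values from every cohort are pooled before the BH step, so adj_p is
    controlled over the whole study, not per cohort.
    """
    frames = []
    for cohort in sorted(samples["cohort"].unique()):
        kept = None if kept_per_cohort is None else kept_per_cohort[cohort]
        stats_tbl = mean_usage_change(usage, samples, cohort)
        p = test_dtu(usage, samples, cohort, kept)
        tbl = stats_tbl.loc[p.index].copy()
        tbl["p"] = p
        tbl["cohort"] = cohort
        tbl["gene_id"] = annotation.reindex(p.index).to_numpy()
        tbl = tbl.rename_axis("transcript_id").reset_index()
        frames.append(tbl)
    result = pd.concat(frames, ignore_index=True)
    result["adj_p"] = adjust_global(result["p"].to_numpy())
    result["usage_direction"] = label_usage_direction(
        result["dIF"].to_numpy(), result["adj_p"].to_numpy(), config
    )
    return result[DTU_COLUMNS]


def label_usage_direction(
    dif: np.ndarray, adj_p: np.ndarray, config: AnalysisConfig
) -> np.ndarray:
    """up / down / none labels from dIF and adjusted p per the switch definition."""
    significant = adj_p < config.alpha
    direction = np.where(
        significant & (dif > config.dif_threshold), "up",
        np.where(significant & (dif < -config.dif_threshold), "down", "none"),
    )
    return direction


def load_external_dtu(
    path: str | Path,
    usage: pd.DataFrame,
    annotation: pd.Series,
    samples: pd.DataFrame,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Load externally produced DTU p-values and rebuild the DTU table.

    The TSV must carry transcript_id, cohort, and p columns; adj_p is
    recomputed globally with BH when absent. Mean usages and dIF are always
    recomputed from the supplied usage matrix so downstream stages see a
    complete, internally consistent table.
    """
    ext = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "cohort": str})
    required = {"transcript_id", "cohort", "p"}
    missing = required - set(ext.columns)
    if missing:
        raise ValueError(f"external DTU table missing columns: {sorted(missing)}")
    frames = []
    for cohort, sub in ext.groupby("cohort"):
        stats_tbl = mean_usage_change(usage, samples, cohort)
        idx = pd.Index(sub["transcript_id"])
        unknown = idx.difference(stats_tbl.index)
        if len(unknown):
            raise ValueError(
                f"external DTU transcript {unknown[0]!r} not in usage matrix"
            )
        tbl = stats_tbl.loc[idx].copy()
        tbl["p"] = sub["p"].to_numpy(dtype=float)
        if "adj_p" in ext.columns:
            tbl["adj_p"] = sub["adj_p"].to_numpy(dtype=float)
        tbl["cohort"] = cohort
        tbl["gene_id"] = annotation.reindex(idx).to_numpy()
        frames.append(tbl.rename_axis("transcript_id").reset_index())
    result = pd.concat(frames, ignore_index=True)
    if "adj_p" not in result.columns:
        result["adj_p"] = adjust_global(result["p"].to_numpy())
    result["usage_direction"] = label_usage_direction(
        result["dIF"].to_numpy(), result["adj_p"].to_numpy(), config
    )
    return result[DTU_COLUMNS]
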