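"""Transcript-level fold changes and differential transcript expression.

Fold changes are log2 ratios of condition-wise mean TPM with a symmetric
pseudocount. The DE call itself depends only on the adjusted p-value of the
statistical test, never on the fold-change magnitude; the fold change only
supplies the direction label for transcripts that are called DE. The
built-in test is a two-sided rank-sum test on per-sample log2(TPM +
pseudocount); external DTE tables (e.g. from a negative-binomial
quasi-likelihood fit) can be loaded instead, keeping their fold changes
verbatim.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import ExpressionMatrix
from .stats import adjust_global, rank_sum_test_rows
from .usage import _cohort_groups

DTE_COLUMNS = [
    "transcript_id", "gene_id", "cohort", "log2fc", "p", "adj_p",
    "de_flag", "expr_direction",
]


def log2_fold_change(
    tpm: ExpressionMatrix,
    samples: pd.DataFrame,
    cohort: str,
    pseudocount: float = 0.01,
) -> pd.Series:
    """log2((mean cancer TPM + pc) / (mean normal TPM + pc)) per transcript."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    normal_ids, cancer_ids = _cohort_groups(samples, cohort)
    mean_normal = tpm.values[normal_ids].mean(axis=1)
    mean_cancer = tpm.values[cancer_ids].mean(axis=1)
    # difference of logs rather than log of ratio: exact antisymmetry
    # under swapping of the condition labels
    lfc = np.log2(mean_cancer + pseudocount) - np.log2(mean_normal + pseudocount)
    lfc.name = "log2fc"
    return lfc


def test_dte(
    tpm: ExpressionMatrix,
    samples: pd.DataFrame,
    cohort: str,
    kept: set[str] | None = None,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Two-sided rank-sum p-values on per-sample log2(TPM + pseudocount)."""
    normal_ids, cancer_ids = _cohort_groups(samples, cohort)
    if kept is None:
        index = tpm.values.index
    else:
        index = tpm.values.index[tpm.values.index.isin(kept)]
    log_expr = np.log2(tpm.values.loc[index] + pseudocount)
    X = log_expr[cancer_ids].to_numpy()
    Y = log_expr[normal_ids].to_numpy()
    p = rank_sum_test_rows(X, Y)
    return pd.Series(p, index=index, name="p")


def _finalize(result: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    result["de_flag"] = result["adj_p"] < config.alpha
    sign = np.sign(result["log2fc"].to_numpy())
    result["expr_direction"] = np.where(
        result["de_flag"] & (sign > 0), "up",
        np.where(result["de_flag"] & (sign < 0), "down", "none"),
    )
    return result[DTE_COLUMNS]


def run_dte(
    tpm: ExpressionMatrix,
    annotation: pd.Series,
    samples: pd.DataFrame,
    kept_per_cohort: dict[str, set[str]] | None,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Full DTE table over all cohorts with global BH adjustment.

    Tested on the same kept transcript sets as the DTU stage, so the two
    result tables describe the identical transcript universe.
    """
    frames = []
    for cohort in sorted(samples["cohort"].unique()):
        kept = None if kept_per_cohort is None else kept_per_cohort[cohort]
        p = test_dte(tpm, samples, cohort, kept, config.pseudocount)
        lfc = log2_fold_change(tpm, samples, cohort, config.pseudocount)
        tbl = pd.DataFrame({"log2fc": lfc.loc[p.index], "p": p})
        tbl["cohort"] = cohort
        tbl["gene_id"] = annotation.reindex(p.index).to_numpy()
        frames.append(tbl.rename_axis("transcript_id").reset_index())
    result = pd.concat(frames, ignore_index=True)
    result["adj_p"] = adjust_global(result["p"].to_numpy())
    return _finalize(result, config)


def load_external_dte(
    path: str | Path,
    annotation: pd.Series,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Load externally produced DTE results (log2fc kept verbatim).

    Requires transcript_id, cohort, log2fc, and p columns; adj_p is
    recomputed globally with BH when absent.
    """
    ext = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "cohort": str})
    required = {"transcript_id", "cohort", "log2fc", "p"}
    missing = required - set(ext.columns)
    if missing:
        raise ValueError(f"external DTE table missing columns: {sorted(missing)}")
    result = ext.copy()
    result["log2fc"] = result["log2fc"].astype(float)
    result["p"] = result["p"].astype(float)
    result["gene_id"] = annotation.reindex(
        pd.Index(result["transcript_id"])
    ).to_numpy()
    if "adj_p" not in result.columns:
        result["adj_p"] = adjust_global(result["p"].to_numpy())
    else:
        result["adj_p"] = result["adj_p"].astype(float)
    return _finalize(result, config)
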