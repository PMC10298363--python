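"""Switch prioritization: the filter chain and the auxiliary filters.

The core chain narrows the quantified switch list to events most likely to
pair transcripts with genuinely opposite behavior:

1. keep only concordant switches (both transcripts DE, expression changes
   codirectional with usage changes);
2. drop switches with combined frequency 0 (one transcript out-expresses
   the other in every sample of some condition);
3. optionally require the combined frequency strictly above a cutoff
   (0.5 is the recommended stringent setting);
4. optionally require both |log2fc| strictly above a cutoff (disabled by
   default).

Survivors are ranked by combined frequency, descending, with a
deterministic lexicographic tie-break. Boundary semantics: strict ``>``
for combined frequency and fold change ("higher than"), ``>=`` for the
TPM floor of the auxiliary expression filter.

Two further filters reproduce the prevalence-reversal post-processing of
the frequency-based switch definition: a mean-expression floor (both
transcripts at or above 1 TPM in cancer or in normal samples) and a usage
anti-correlation requirement (Spearman rho of the two transcripts' usage
vectors below -0.8 across all of the cohort's samples).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import ExpressionMatrix
from .stats import spearman
from .usage import _cohort_groups

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Stage-wise accounting of the prioritization chain."""

    stages: list[dict] = field(default_factory=list)
    ranked: pd.DataFrame | None = None

    def add_stage(self, name: str, rule: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError("a filter stage cannot grow the switch list")
        if self.stages and self.stages[-1]["n_out"] != n_in:
            raise ValueError("stage input must equal previous stage output")
        self.stages.append(
            {"stage": name, "rule": rule, "n_in": int(n_in), "n_out": int(n_out)}
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"stages": self.stages}, indent=2))


def rank_switches(switches: pd.DataFrame) -> pd.DataFrame:
    """Order by combined frequency descending; lexicographic tie-break."""
    out = switches.sort_values(
        ["combined_freq", "gene_id", "cancer_tx", "normal_tx"],
        ascending=[False, True, True, True],
        kind="stable",
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def filter_chain(switches: pd.DataFrame, config: AnalysisConfig) -> FilterReport:
    """Apply the prioritization chain; returns stage accounting + ranked list."""
    required = {"concordance_class", "combined_freq", "log2fc_cancer",
                "log2fc_normal"}
    missing = required - set(switches.columns)
    if missing:
        raise ValueError(f"switches not quantified: missing {sorted(missing)}")
    report = FilterReport()
    current = switches

    kept = current[current["concordance_class"] == "concordant"]
    report.add_stage(
        "concordant_only",
        "both transcripts DE with expression codirectional to usage",
        len(current), len(kept),
    )
    current = kept

    kept = current[current["combined_freq"] > 0]
    report.add_stage(
        "nonzero_combined_frequency",
        "drop combined frequency = 0",
        len(current), len(kept),
    )
    current = kept

    if config.min_combined_freq > 0:
        kept = current[current["combined_freq"] > config.min_combined_freq]
        report.add_stage(
            "min_combined_frequency",
            f"combined frequency > {config.min_combined_freq}",
            len(current), len(kept),
        )
        current = kept

    if config.lfc_filter_enabled:
        min_abs_lfc = np.minimum(
            current["log2fc_cancer"].abs(), current["log2fc_normal"].abs()
        )
        kept = current[min_abs_lfc > config.lfc_filter]
        report.add_stage(
            "min_abs_log2fc",
            f"both |log2fc| > {config.lfc_filter}",
            len(current), len(kept),
        )
        current = kept

    report.ranked = rank_switches(current)
    return report


def expression_floor_filter(
    switches: pd.DataFrame,
    tpm: ExpressionMatrix,
    samples: pd.DataFrame,
    floor_tpm: float = 1.0,
) -> pd.DataFrame:
    """Keep switches whose transcripts each reach the TPM floor somewhere.

    Each transcript must have mean TPM >= ``floor_tpm`` in the cohort's
    cancer samples or in its normal samples (boundary inclusive).
    """
    keep = np.ones(len(switches), dtype=bool)
    group_cache: dict[str, tuple[list[str], list[str]]] = {}
    values = tpm.values
    for i, row in enumerate(switches.itertuples(index=False)):
        if row.cohort not in group_cache:
            group_cache[row.cohort] = _cohort_groups(samples, row.cohort)
        normal_ids, cancer_ids = group_cache[row.cohort]
        for tx in (row.cancer_tx, row.normal_tx):
            mean_n = values.loc[tx, normal_ids].mean()
            mean_c = values.loc[tx, cancer_ids].mean()
            if not (mean_n >= floor_tpm or mean_c >= floor_tpm):
                keep[i] = False
                break
    return switches[keep].reset_index(drop=True)


def anticorrelation_filter(
    switches: pd.DataFrame,
    usage: pd.DataFrame,
    samples: pd.DataFrame,
    rho_threshold: float = -0.8,
) -> pd.DataFrame:
    """Keep switches with strongly anti-correlated usage vectors.

    Spearman rho of the two transcripts' per-sample usage values across all
    of the cohort's samples (both conditions pooled) must be strictly below
    ``rho_threshold``. Switches with an undefined correlation (a constant
    usage vector) are dropped with a warning.
    """
    keep = np.zeros(len(switches), dtype=bool)
    group_cache: dict[str, list[str]] = {}
    for i, row in enumerate(switches.itertuples(index=False)):
        if row.cohort not in group_cache:
            normal_ids, cancer_ids = _cohort_groups(samples, row.cohort)
            group_cache[row.cohort] = normal_ids + cancer_ids
        ids = group_cache[row.cohort]
        rho = spearman(
            usage.loc[row.cancer_tx, ids].to_numpy(),
            usage.loc[row.normal_tx, ids].to_numpy(),
        )
        if np.isnan(rho):
            logger.warning(
                "switch (%s, %s, %s) dropped: usage correlation undefined",
                row.gene_id, row.cancer_tx, row.normal_tx,
            )
            continue
        keep[i] = rho < rho_threshold
    return switches[keep].reset_index(drop=True)
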