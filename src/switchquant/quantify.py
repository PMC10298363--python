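"""Concordance classification, characteristic frequencies, and summaries.

Each switch is classified by how its two transcripts' expression changes
relate to their usage changes. The cancer transcript is up-used and the
normal transcript down-used by construction; their DE status and expression
direction then yield seven mutually exclusive classes:

================  ==========================================================
concordant        both DE; cancer tx up, normal tx down in expression
reverse           both DE; cancer tx down, normal tx up (expression opposes
                  usage for both)
both_down         both DE, both decreasing expression
both_up           both DE, both increasing expression
cancer_not_de     cancer transcript not DE, normal transcript DE
normal_not_de     normal transcript not DE, cancer transcript DE
both_not_de       neither DE (impossible in expectation when both usage
                  shifts are real, since equal expression changes cannot
                  produce opposite usage changes)
================  ==========================================================

Each switch also gets two characteristic frequencies: f_cancer, the share
of cancer samples where the cancer transcript out-expresses the normal
transcript, and f_normal, the share of normal samples with the reverse
order. Their product is the combined frequency used for ranking; the sum
minus one is kept as the legacy score. A sample with exactly equal
expression of the two transcripts counts toward neither frequency (strict
inequality) — measure-zero for continuous TPM but relevant when both are 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .stats import (adjust_global, rank_sum_test, signed_rank_test, spearman)
from .usage import _cohort_groups

logger = logging.getLogger(__name__)

CONCORDANCE_CLASSES = (
    "concordant", "cancer_not_de", "normal_not_de", "both_not_de",
    "both_down", "both_up", "reverse",
)


def _class_from_flags(
    de_cancer: bool, dir_cancer: str, de_normal: bool, dir_normal: str
) -> str:
    if not de_cancer and not de_normal:
        return "both_not_de"
    if not de_cancer:
        return "cancer_not_de"
    if not de_normal:
        return "normal_not_de"
    if dir_cancer == "up" and dir_normal == "down":
        return "concordant"
    if dir_cancer == "down" and dir_normal == "up":
        return "reverse"
    return "both_up" if dir_cancer == "up" else "both_down"


def classify_switch(sw, dte: pd.DataFrame) -> str:
    """Concordance class of one switch given the DTE table.

    ``sw`` is any mapping with gene-independent keys cohort, cancer_tx and
    normal_tx (a Switch table row works).
    """
    indexed = dte.set_index(["transcript_id", "cohort"])
    rows = {}
    for role, tx in (("cancer", sw["cancer_tx"]), ("normal", sw["normal_tx"])):
        try:
            rows[role] = indexed.loc[(tx, sw["cohort"])]
        except KeyError:
            raise ValueError(
                f"no DTE result for transcript {tx!r} in cohort {sw['cohort']!r}"
            ) from None
    return _class_from_flags(
        bool(rows["cancer"]["de_flag"]), str(rows["cancer"]["expr_direction"]),
        bool(rows["normal"]["de_flag"]), str(rows["normal"]["expr_direction"]),
    )


def classify_switches(switches: pd.DataFrame, dte: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification; adds concordance_class and both log2fc columns."""
    if len(switches) == 0:
        out = switches.copy()
        for col in ("concordance_class", "log2fc_cancer", "log2fc_normal"):
            out[col] = pd.Series(dtype=float if "log2fc" in col else object)
        return out
    dte_idx = dte.set_index(["transcript_id", "cohort"])

    def _lookup(tx_col: str, field: str) -> np.ndarray:
        keys = list(zip(switches[tx_col], switches["cohort"]))
        try:
            return dte_idx.loc[keys, field].to_numpy()
        except KeyError as err:
            raise ValueError(f"missing DTE result for {err.args[0]!r}") from None

    de_c = _lookup("cancer_tx", "de_flag").astype(bool)
    de_n = _lookup("normal_tx", "de_flag").astype(bool)
    dir_c = _lookup("cancer_tx", "expr_direction")
    dir_n = _lookup("normal_tx", "expr_direction")
    out = switches.copy()
    out["concordance_class"] = [
        _class_from_flags(a, b, c, d) for a, b, c, d in zip(de_c, dir_c, de_n, dir_n)
    ]
    out["log2fc_cancer"] = _lookup("cancer_tx", "log2fc").astype(float)
    out["log2fc_normal"] = _lookup("normal_tx", "log2fc").astype(float)
    _log_unexpected_classes(out)
    return out


def _log_unexpected_classes(switches: pd.DataFrame) -> None:
    for cls in ("both_not_de", "reverse"):
        n = int((switches["concordance_class"] == cls).sum())
        if n:
            logger.warning(
                "%d switches classified %s; this class is expected empty when "
                "both usage shifts are genuine", n, cls,
            )


def switch_frequencies(
    switches: pd.DataFrame,
    expr: ExpressionMatrix | pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Characteristic frequencies and the combined/legacy scores per switch.

    ``expr`` may be the TPM matrix or the usage matrix: whenever the parent
    gene is expressed in every sample the within-gene expression order is
    unchanged by the usage normalization, so the frequencies agree.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    out = switches.copy()
    f_cancer = np.empty(len(out))
    f_normal = np.empty(len(out))
    group_cache: dict[str, tuple[list[str], list[str]]] = {}
    for i, row in enumerate(out.itertuples(index=False)):
        if row.cohort not in group_cache:
            group_cache[row.cohort] = _cohort_groups(samples, row.cohort)
        normal_ids, cancer_ids = group_cache[row.cohort]
        expr_c = values.loc[row.cancer_tx]
        expr_n = values.loc[row.normal_tx]
        f_cancer[i] = float(
            (expr_c[cancer_ids].to_numpy() > expr_n[cancer_ids].to_numpy()).mean()
        )
        f_normal[i] = float(
            (expr_n[normal_ids].to_numpy() > expr_c[normal_ids].to_numpy()).mean()
        )
    out["f_cancer"] = f_cancer
    out["f_normal"] = f_normal
    out["combined_freq"] = out["f_cancer"] * out["f_normal"]
    out["legacy_score"] = out["f_cancer"] + out["f_normal"] - 1.0
    return out


def frequency_curve(switches: pd.DataFrame, step: float = 0.01) -> pd.DataFrame:
    """Survival curves of the frequencies over a threshold grid.

    For each threshold t in [0, 1]: the share of switches whose *larger*
    characteristic frequency is >= t, and the share whose combined
    frequency is >= t. Both curves are monotone non-increasing.
    """
    if len(switches) == 0:
        return pd.DataFrame(
            columns=["threshold", "prop_max_frequency", "prop_combined"]
        )
    thresholds = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    fmax = np.maximum(switches["f_cancer"].to_numpy(),
                      switches["f_normal"].to_numpy())
    combined = switches["combined_freq"].to_numpy()
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "prop_max_frequency": [(fmax >= t).mean() for t in thresholds],
            "prop_combined": [(combined >= t).mean() for t in thresholds],
        }
    )


def class_summary(switches: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per concordance class, per cohort and pooled."""
    frames = []
    scopes = [("pooled", switches)]
    scopes += [(c, sub) for c, sub in switches.groupby("cohort")]
    for scope, sub in scopes:
        counts = sub["concordance_class"].value_counts()
        total = len(sub)
        for cls in CONCORDANCE_CLASSES:
            n = int(counts.get(cls, 0))
            frames.append(
                {
                    "cohort": scope,
                    "concordance_class": cls,
                    "n": n,
                    "percent": 100.0 * n / total if total else 0.0,
                }
            )
    return pd.DataFrame(frames)


def transcript_role_summary(
    switches: pd.DataFrame, dte: pd.DataFrame
) -> pd.DataFrame:
    """Per-role DE composition, counting each transcript once per cohort.

    Reports, for cancer and for normal transcripts separately, how many are
    not DE, DE with expression opposing their usage direction, and DE with
    expression matching it.
    """
    dte_idx = dte.set_index(["transcript_id", "cohort"])
    rows = []
    for role, tx_col, with_usage in (
        ("cancer", "cancer_tx", "up"),
        ("normal", "normal_tx", "down"),
    ):
        uniq = switches[[tx_col, "cohort"]].drop_duplicates()
        keys = list(zip(uniq[tx_col], uniq["cohort"]))
        de = dte_idx.loc[keys, "de_flag"].to_numpy(dtype=bool)
        direction = dte_idx.loc[keys, "expr_direction"].to_numpy()
        n = len(uniq)
        n_not_de = int((~de).sum())
        n_opposite = int((de & (direction != with_usage)).sum())
        n_matching = int((de & (direction == with_usage)).sum())
        for label, count in (
            ("not_de", n_not_de),
            ("de_opposite_direction", n_opposite),
            ("de_matching_direction", n_matching),
        ):
            rows.append(
                {
                    "role": role,
                    "category": label,
                    "n": count,
                    "percent": 100.0 * count / n if n else 0.0,
                    "n_transcripts": n,
                }
            )
    return pd.DataFrame(rows)


def _switch_transcript_table(
    switches: pd.DataFrame, dtu: pd.DataFrame, dte: pd.DataFrame
) -> pd.DataFrame:
    """Long per-(transcript, role, cohort) table for the stratified analyses."""
    parts = []
    for role, tx_col in (("cancer", "cancer_tx"), ("normal", "normal_tx")):
        sub = switches[[tx_col, "cohort", "gene_id"]].drop_duplicates()
        sub = sub.rename(columns={tx_col: "transcript_id"})
        sub["role"] = role
        parts.append(sub)
    long = pd.concat(parts, ignore_index=True)
    long = long.merge(
        dtu[["transcript_id", "cohort", "dIF"]], on=["transcript_id", "cohort"]
    )
    long = long.merge(
        dte[["transcript_id", "cohort", "log2fc"]], on=["transcript_id", "cohort"]
    )
    return long


def stratify_by_expression(
    results: pd.DataFrame,
    tpm: ExpressionMatrix,
    samples: pd.DataFrame,
    threshold_tpm: float = 1.0,
) -> pd.DataFrame:
    """Compare dIF and log2fc between lowly and highly expressed transcripts.

    ``results`` is the long per-(transcript, role, cohort) table produced by
    the pipeline (columns transcript_id, cohort, role, dIF, log2fc).
    Transcripts are split at ``threshold_tpm`` on their mean TPM in the
    cohort's *normal* samples — the reference state all changes are
    measured against. Rank-sum comparisons per role and metric are
    BH-adjusted together; empty groups skip the comparison with a warning.
    """
    results = results.reset_index(drop=True).copy()
    mean_normal = np.empty(len(results))
    for cohort, sub in results.groupby("cohort"):
        normal_ids, _ = _cohort_groups(samples, cohort)
        mean_normal[sub.index] = (
            tpm.values.loc[sub["transcript_id"], normal_ids].mean(axis=1).to_numpy()
        )
    results["mean_tpm_normal"] = mean_normal
    results["expression_group"] = np.where(
        results["mean_tpm_normal"] < threshold_tpm, "low", "high"
    )
    rows = []
    for role, sub in results.groupby("role"):
        low = sub[sub["expression_group"] == "low"]
        high = sub[sub["expression_group"] == "high"]
        for metric in ("dIF", "log2fc"):
            if len(low) == 0 or len(high) == 0:
                logger.warning(
                    "stratified comparison skipped for role=%s metric=%s: "
                    "empty group (low=%d, high=%d)",
                    role, metric, len(low), len(high),
                )
                continue
            p = rank_sum_test(low[metric].to_numpy(), high[metric].to_numpy())
            rows.append(
                {
                    "role": role,
                    "metric": metric,
                    "n_low": len(low),
                    "n_high": len(high),
                    "median_low": float(low[metric].median()),
                    "median_high": float(high[metric].median()),
                    "median_diff_high_minus_low": float(
                        high[metric].median() - low[metric].median()
                    ),
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = adjust_global(out["p"].to_numpy())
    return out


def expression_effect_correlation(
    results: pd.DataFrame,
    tpm: ExpressionMatrix,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman correlation of baseline expression with effect sizes, per role.

    Correlates each switch transcript's mean TPM in normal samples with its
    dIF and with its log2fc. Undefined correlations (constant input, fewer
    than 3 transcripts) are reported as NaN.
    """
    results = results.reset_index(drop=True).copy()
    mean_normal = np.empty(len(results))
    for cohort, sub in results.groupby("cohort"):
        normal_ids, _ = _cohort_groups(samples, cohort)
        mean_normal[sub.index] = (
            tpm.values.loc[sub["transcript_id"], normal_ids].mean(axis=1).to_numpy()
        )
    results["mean_tpm_normal"] = mean_normal
    rows = []
    for role, sub in results.groupby("role"):
        for metric in ("dIF", "log2fc"):
            rho = (
                spearman(sub["mean_tpm_normal"].to_numpy(), sub[metric].to_numpy())
                if len(sub) >= 3
                else float("nan")
            )
            rows.append(
                {"role": role, "metric": metric, "n": len(sub), "spearman_rho": rho}
            )
    return pd.DataFrame(rows)


def cohort_comparisons(
    switches: pd.DataFrame, transcript_results: pd.DataFrame
) -> pd.DataFrame:
    """The cross-cohort and within-cohort test battery, BH-adjusted globally.

    (a) Kruskal-Wallis across cohorts on dIF and log2fc, per transcript
    role; (b) paired two-sided signed-rank of |dIF_cancer| vs |dIF_normal|
    within each cohort; (c) one-sided signed-rank within the both_down and
    both_up classes testing whether the normal transcript's expression
    change is the smaller one (more negative in both_down, smaller increase
    in both_up).
    """
    from scipy import stats as sps

    rows = []
    cohorts = sorted(transcript_results["cohort"].unique())
    for role, sub in transcript_results.groupby("role"):
        for metric in ("dIF", "log2fc"):
            groups = [
                sub.loc[sub["cohort"] == c, metric].to_numpy() for c in cohorts
            ]
            groups = [g for g in groups if len(g)]
            if len(groups) < 2:
                continue
            if np.ptp(np.concatenate(groups)) == 0:
                p = 1.0
            else:
                p = float(sps.kruskal(*groups).pvalue)
            rows.append(
                {
                    "test": "kruskal_wallis_across_cohorts",
                    "scope": f"role={role}, metric={metric}",
                    "n": int(sum(len(g) for g in groups)),
                    "p": p,
                }
            )
    for cohort, sub in switches.groupby("cohort"):
        if len(sub) == 0:
            continue
        p = signed_rank_test(
            np.abs(sub["dIF_cancer"].to_numpy()),
            np.abs(sub["dIF_normal"].to_numpy()),
        )
        rows.append(
            {
                "test": "signed_rank_abs_dif_cancer_vs_normal",
                "scope": f"cohort={cohort}",
                "n": len(sub),
                "p": p,
            }
        )
    for cls in ("both_down", "both_up"):
        sub = switches[switches.get("concordance_class", pd.Series(dtype=object)) == cls]
        if len(sub) == 0:
            continue
        p = signed_rank_test(
            sub["log2fc_normal"].to_numpy(),
            sub["log2fc_cancer"].to_numpy(),
            alternative="less",
        )
        rows.append(
            {
                "test": "signed_rank_normal_lfc_less_than_cancer",
                "scope": f"class={cls}",
                "n": len(sub),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = adjust_global(out["p"].to_numpy())
    return out
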