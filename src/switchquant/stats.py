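"""Shared statistical primitives: rank tests and global FDR adjustment.

The built-in two-group test throughout the package is the two-sided
Mann-Whitney (Wilcoxon rank-sum) test. For small problems (combined n of 20
or fewer) the null distribution is enumerated exactly over all group
assignments, which also handles ties exactly; larger problems use the
tie-corrected normal approximation without a continuity correction. The
continuity correction is deliberately omitted on the asymptotic path: for a
discrete statistic it makes p-values systematically conservative, while the
uncorrected approximation tracks the mid-p and keeps null p-values uniform
in aggregate — which matters here because p-values are pooled across all
cohorts for the global FDR step. Groups that are jointly constant have no
information about a location shift, and get p = 1 by convention.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Combined sample size at or below which the exact permutation null is used.
EXACT_N_MAX = 20

# C(20, 10) = 184756 distinct assignments; anything above this budget would
# already be on the asymptotic path.
_EXACT_METHOD = stats.PermutationMethod(n_resamples=200_000)


def rank_sum_test(x, y, alternative: str = "two-sided") -> float:
    """Mann-Whitney rank-sum p-value for one pair of groups.

    Exact enumeration for combined n <= 20, tie- and continuity-corrected
    normal approximation otherwise. Jointly constant input gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    if x.size + y.size <= EXACT_N_MAX:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method=_EXACT_METHOD)
    else:
        res = stats.mannwhitneyu(x, y, alternative=alternative,
                                 method="asymptotic", use_continuity=False)
    return float(min(res.pvalue, 1.0))


def rank_sum_test_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for matrices of groups.

    ``X`` and ``Y`` are (tests x samples) arrays for the two conditions.
    Small problems fall back to the exact scalar path row by row.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] + Y.shape[1] <= EXACT_N_MAX:
        return np.array([rank_sum_test(x, y) for x, y in zip(X, Y)])
    constant = (np.ptp(X, axis=1) == 0) & (np.ptp(Y, axis=1) == 0)
    constant &= X[:, 0] == Y[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(X, Y, axis=1, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        p = np.asarray(res.pvalue, dtype=float)
    p[constant] = 1.0
    # remaining NaNs can only come from degenerate tie structure
    p = np.where(np.isnan(p), 1.0, p)
    return np.minimum(p, 1.0)


def adjust_global(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment over the pooled p-values.

    The pipeline pools p-values across all cohorts before calling this, so
    the FDR guarantee is global rather than per cohort.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def signed_rank_test(x, y, alternative: str = "two-sided") -> float:
    """Paired Wilcoxon signed-rank p-value; all-zero differences give p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.all(d == 0):
        return 1.0
    res = stats.wilcoxon(x, y, alternative=alternative, zero_method="wilcox")
    return float(min(res.pvalue, 1.0))


def spearman(x, y) -> float:
    """Spearman rank correlation with midrank ties; NaN when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)
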