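"""Synthetic two-condition transcript-level cohorts with planted switches.

The generator emulates the statistical structure of bulk tumor/normal
RNA-seq at the transcript level: genes carry 2-5 isoforms whose baseline
usage proportions are drawn from a symmetric Dirichlet, gene-level
abundances are log-normal, and per-sample transcript counts are negative
binomial around the expected abundance. Planted isoform switches move a
fixed amount of usage mass (``delta_if``) from a designated "normal"
transcript to a designated "cancer" transcript in the cancer condition,
while a gene-level fold change positions the pair in one of the
usage/expression concordance classes:

``concordant``
    gene fold inside the open interval that makes the cancer transcript's
    expected expression rise and the normal transcript's fall (1.0 always
    qualifies);
``cancer_not_de`` / ``normal_not_de``
    gene fold solved exactly so that one transcript's expected expression
    is identical across conditions while the other changes;
``both_down`` / ``both_up``
    gene fold scaled so that both transcripts' expected expression falls
    (rises), the cancer transcript by exactly the requested ``gene_fold``
    factor in the down case, the normal transcript in the up case.

Counts are drawn per sample; TPM is then recomputed from counts by column
normalization to 1e6, so the emitted TPM matrix carries the same sampling
noise (and mild compositional coupling) as the counts. Transcript lengths
are treated as equal, so counts are proportional to TPM.

All gene-level structure is drawn from per-gene seeded streams, which makes
``expected_class`` an independent, purely algebraic oracle: it recomputes a
planted pair's expected expressions from the spec alone and reads the class
off the fold ratios.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

EXPRESSION_CLASSES = (
    "concordant",
    "cancer_not_de",
    "normal_not_de",
    "both_down",
    "both_up",
)

#: Default gene-level fold change per expression class, used when a planted
#: switch does not specify one. The not-DE classes solve their fold exactly
#: and ignore it.
DEFAULT_GENE_FOLD = {
    "concordant": 1.0,
    "cancer_not_de": 1.0,
    "normal_not_de": 1.0,
    "both_down": 0.5,
    "both_up": 1.5,
}

_USAGE_MARGIN = 0.05  # head-room kept around usage bounds when planting
_USAGE_FLOOR = 0.01


@dataclass
class PlantedSwitch:
    """One planted isoform switch.

    ``cancer_tx``/``normal_tx`` may be left as None, in which case the
    generator designates the gene's two highest-baseline-usage isoforms:
    the most used one becomes the normal transcript (the one losing usage
    in cancer) and the runner-up becomes the cancer transcript.
    """

    gene_id: str
    cancer_tx: str | None = None
    normal_tx: str | None = None
    delta_if: float = 0.3
    expression_class: str = "concordant"
    gene_fold: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.delta_if < 1:
            raise ValueError("delta_if must be in (0, 1)")
        if self.expression_class not in EXPRESSION_CLASSES:
            raise ValueError(
                f"unknown expression_class {self.expression_class!r}; "
                f"allowed: {EXPRESSION_CLASSES}"
            )
        if self.gene_fold is not None and self.gene_fold <= 0:
            raise ValueError("gene_fold must be > 0")


@dataclass
class ScenarioSpec:
    """Parameters of one simulated cohort.

    Defaults mirror a modest tumor/normal bulk RNA-seq cohort: 25 samples
    per condition (the minimum cohort size the analysis is designed for),
    2-5 isoforms per gene, log-normal gene abundances with natural-log mean
    4 (median ~55 TPM) and sd 1, negative-binomial counts with size 10, and
    2 million assigned reads per sample.
    """

    n_genes: int = 100
    isoforms_per_gene: tuple[int, int] = (2, 5)
    n_normal: int = 25
    n_cancer: int = 25
    planted: list[PlantedSwitch] = field(default_factory=list)
    dispersion: float = 10.0
    mean_gene_tpm_log_mu: float = 4.0
    log_sigma: float = 1.0
    library_size: int = 2_000_000
    seed: int = 0
    cohort: str = "SIM"
    balance_composition: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.isoforms_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("isoforms_per_gene must be an increasing range >= 1")
        if self.n_genes < 1 or self.n_normal < 1 or self.n_cancer < 1:
            raise ValueError("n_genes and group sizes must be positive")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0 (np.inf disables noise)")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GeneModel:
    """Expected (noise-free) structure of one simulated gene."""

    gene_id: str
    transcripts: list[str]
    usage_normal: np.ndarray  # baseline usage, sums to 1
    usage_cancer: np.ndarray  # after any planted mass transfer, sums to 1
    gene_tpm: float  # expected gene TPM in normal samples
    gene_fold: float  # effective multiplier on gene TPM in cancer

    @property
    def tpm_normal(self) -> np.ndarray:
        return self.gene_tpm * self.usage_normal

    @property
    def tpm_cancer(self) -> np.ndarray:
        return self.gene_tpm * self.gene_fold * self.usage_cancer


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, 0, gene_index])


def _baseline_gene(spec: ScenarioSpec, gene_index: int, gene_id: str) -> GeneModel:
    rng = _gene_rng(spec.seed, gene_index)
    lo, hi = spec.isoforms_per_gene
    k = int(rng.integers(lo, hi + 1))
    usage = rng.dirichlet(np.full(k, 2.0))
    usage = np.maximum(usage, _USAGE_FLOOR)
    usage = usage / usage.sum()
    gene_tpm = float(np.exp(rng.normal(spec.mean_gene_tpm_log_mu, spec.log_sigma)))
    transcripts = [f"{gene_id}.T{j}" for j in range(1, k + 1)]
    return GeneModel(
        gene_id=gene_id,
        transcripts=transcripts,
        usage_normal=usage,
        usage_cancer=usage.copy(),
        gene_tpm=gene_tpm,
        gene_fold=1.0,
    )


def _resolve_pair(model: GeneModel, plant: PlantedSwitch) -> tuple[int, int]:
    if plant.normal_tx is None or plant.cancer_tx is None:
        order = np.argsort(-model.usage_normal, kind="stable")
        i_normal, i_cancer = int(order[0]), int(order[1])
    else:
        try:
            i_cancer = model.transcripts.index(plant.cancer_tx)
            i_normal = model.transcripts.index(plant.normal_tx)
        except ValueError as err:
            raise ValueError(
                f"planted transcript not in gene {model.gene_id}: {err}"
            ) from None
    if i_cancer == i_normal:
        raise ValueError(
            f"planted pair for {model.gene_id} must be two distinct isoforms"
        )
    return i_cancer, i_normal


def _ensure_feasible_baseline(
    usage: np.ndarray, i_cancer: int, i_normal: int, delta: float
) -> np.ndarray:
    """Adjust the baseline so the mass transfer keeps usages in [0, 1].

    The normal transcript needs at least ``delta`` usage to give away; any
    shortfall is borrowed proportionally from the other isoforms. Because
    the result sums to 1, the cancer transcript then automatically has room
    to receive ``delta``.
    """
    usage = usage.copy()
    need = delta + _USAGE_MARGIN
    if usage[i_normal] < need:
        if need > 1 - (len(usage) - 1) * _USAGE_FLOOR:
            raise ValueError(
                f"delta_if={delta} infeasible: normal transcript would need "
                f"usage >= {need:.3f}"
            )
        shortfall = need - usage[i_normal]
        others = np.ones(len(usage), dtype=bool)
        others[i_normal] = False
        take = usage[others] - _USAGE_FLOOR
        if take.sum() < shortfall:
            raise ValueError("cannot rebalance baseline usage for planted switch")
        usage[others] -= shortfall * take / take.sum()
        usage[i_normal] = need
        usage = usage / usage.sum()
    return usage


def _effective_fold(
    plant: PlantedSwitch, u_c_n: float, u_c_c: float, u_n_n: float, u_n_c: float
) -> float:
    """Gene-level fold implementing the planted expression class.

    Expected expression ratios (cancer/normal) of the pair are
    ``fold * u_c_c / u_c_n`` for the cancer transcript and
    ``fold * u_n_c / u_n_n`` for the normal transcript; the class
    constrains ``fold`` accordingly.
    """
    cls = plant.expression_class
    lower = u_c_n / u_c_c  # fold at which the cancer transcript is flat
    upper = u_n_n / u_n_c  # fold at which the normal transcript is flat
    g = plant.gene_fold if plant.gene_fold is not None else DEFAULT_GENE_FOLD[cls]
    if cls == "concordant":
        if not lower < g < upper:
            raise ValueError(
                f"concordant switch requires gene_fold in ({lower:.4g}, "
                f"{upper:.4g}); got {g}"
            )
        return g
    if cls == "cancer_not_de":
        return lower
    if cls == "normal_not_de":
        return upper
    if cls == "both_down":
        if not g < 1:
            raise ValueError(
                f"both_down requires gene_fold < 1 (cancer transcript falls by "
                f"that factor); got {g}"
            )
        return g * lower
    if cls == "both_up":
        if not g > 1:
            raise ValueError(
                f"both_up requires gene_fold > 1 (normal transcript rises by "
                f"that factor); got {g}"
            )
        return g * upper
    raise AssertionError(cls)


def build_gene_models(spec: ScenarioSpec) -> tuple[list[GeneModel], pd.DataFrame]:
    """Deterministically build all gene models and the ground-truth table."""
    gene_ids = spec.gene_ids()
    by_gene = {p.gene_id: p for p in spec.planted}
    unknown = set(by_gene) - set(gene_ids)
    if unknown:
        raise ValueError(f"planted genes not in scenario: {sorted(unknown)}")
    if len(by_gene) != len(spec.planted):
        raise ValueError("at most one planted switch per gene is supported")

    models: list[GeneModel] = []
    truth_rows = []
    for gi, gid in enumerate(gene_ids):
        model = _baseline_gene(spec, gi, gid)
        plant = by_gene.get(gid)
        if plant is not None:
            i_c, i_n = _resolve_pair(model, plant)
            base = _ensure_feasible_baseline(
                model.usage_normal, i_c, i_n, plant.delta_if
            )
            cancer = base.copy()
            cancer[i_c] += plant.delta_if
            cancer[i_n] -= plant.delta_if
            model.usage_normal = base
            model.usage_cancer = cancer
            model.gene_fold = _effective_fold(
                plant, base[i_c], cancer[i_c], base[i_n], cancer[i_n]
            )
            truth_rows.append(
                {
                    "gene_id": gid,
                    "cancer_tx": model.transcripts[i_c],
                    "normal_tx": model.transcripts[i_n],
                    "delta_if": plant.delta_if,
                    "expression_class": plant.expression_class,
                    "gene_fold_eff": model.gene_fold,
                    "usage_cancer_tx_normal": base[i_c],
                    "usage_cancer_tx_cancer": cancer[i_c],
                    "usage_normal_tx_normal": base[i_n],
                    "usage_normal_tx_cancer": cancer[i_n],
                    "exp_tpm_cancer_tx_normal": model.tpm_normal[i_c],
                    "exp_tpm_cancer_tx_cancer": model.tpm_cancer[i_c],
                    "exp_tpm_normal_tx_normal": model.tpm_normal[i_n],
                    "exp_tpm_normal_tx_cancer": model.tpm_cancer[i_n],
                    "expected_class": _class_from_ratios(
                        model.tpm_cancer[i_c] / model.tpm_normal[i_c],
                        model.tpm_cancer[i_n] / model.tpm_normal[i_n],
                    ),
                }
            )
        models.append(model)
    if spec.balance_composition and by_gene:
        _balance_background(models, set(by_gene))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id", "cancer_tx", "normal_tx", "delta_if", "expression_class",
            "gene_fold_eff", "usage_cancer_tx_normal", "usage_cancer_tx_cancer",
            "usage_normal_tx_normal", "usage_normal_tx_cancer",
            "exp_tpm_cancer_tx_normal", "exp_tpm_cancer_tx_cancer",
            "exp_tpm_normal_tx_normal", "exp_tpm_normal_tx_cancer",
            "expected_class",
        ],
    )
    return models, truth


def _balance_background(models: list[GeneModel], planted_genes: set[str]) -> None:
    """Equalize expected library composition across conditions.

    Planted fold changes shift the expected total expression of the cancer
    condition; because emitted TPM is column-normalized, such a shift would
    rescale *every* transcript's measured TPM and contaminate the planted
    expression classes (a flat transcript would appear differentially
    expressed). A uniform compensating fold on the unplanted background
    genes restores equal expected totals, so planted expectations survive
    the normalization. No-op when the planted genes are composition-neutral.
    """
    total_normal = sum(m.gene_tpm for m in models)
    planted_cancer = sum(
        m.gene_tpm * m.gene_fold for m in models if m.gene_id in planted_genes
    )
    planted_normal = sum(
        m.gene_tpm for m in models if m.gene_id in planted_genes
    )
    background = total_normal - planted_normal
    if background <= 0:
        warnings.warn(
            "no background genes available to balance library composition; "
            "planted expression classes may be distorted by normalization",
            stacklevel=3,
        )
        return
    factor = (total_normal - planted_cancer) / background
    if factor <= 0:
        raise ValueError(
            "planted switches increase expected expression beyond what the "
            "background can compensate; add background genes or reduce folds"
        )
    for m in models:
        if m.gene_id not in planted_genes:
            m.gene_fold = factor


def _class_from_ratios(ratio_cancer_tx: float, ratio_normal_tx: float,
                       rtol: float = 1e-9) -> str:
    """Concordance class implied by expected expression fold ratios."""
    flat_c = abs(ratio_cancer_tx - 1) <= rtol
    flat_n = abs(ratio_normal_tx - 1) <= rtol
    if flat_c and flat_n:
        return "both_not_de"
    if flat_c:
        return "cancer_not_de"
    if flat_n:
        return "normal_not_de"
    up_c = ratio_cancer_tx > 1
    up_n = ratio_normal_tx > 1
    if up_c and not up_n:
        return "concordant"
    if not up_c and up_n:
        return "reverse"
    return "both_up" if up_c else "both_down"


def expected_class(plant: PlantedSwitch, spec: ScenarioSpec) -> str:
    """Concordance class implied by the generator's expected expressions.

    Recomputes the planted gene's structure from the spec seed alone and
    classifies by the expected cancer/normal expression ratios of the pair —
    an algebraic oracle independent of any generated cohort.
    """
    gene_ids = spec.gene_ids()
    try:
        gi = gene_ids.index(plant.gene_id)
    except ValueError:
        raise ValueError(f"gene {plant.gene_id!r} not in scenario") from None
    model = _baseline_gene(spec, gi, plant.gene_id)
    i_c, i_n = _resolve_pair(model, plant)
    base = _ensure_feasible_baseline(model.usage_normal, i_c, i_n, plant.delta_if)
    cancer = base.copy()
    cancer[i_c] += plant.delta_if
    cancer[i_n] -= plant.delta_if
    fold = _effective_fold(plant, base[i_c], cancer[i_c], base[i_n], cancer[i_n])
    ratio_c = fold * cancer[i_c] / base[i_c]
    ratio_n = fold * cancer[i_n] / base[i_n]
    return _class_from_ratios(ratio_c, ratio_n)


def _draw_counts(
    expected_tpm: np.ndarray, spec: ScenarioSpec, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial counts around expected TPM x library share."""
    mean = expected_tpm / 1e6 * spec.library_size
    if not np.isfinite(spec.dispersion):
        return mean.copy()
    size = spec.dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def generate_cohort(
    spec: ScenarioSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Generate one cohort: (counts, tpm, annotation, sample sheet, truth).

    Identical specs (including seed) give bit-identical outputs. TPM is
    recomputed from the drawn counts by normalizing each sample to 1e6.
    """
    models, truth = build_gene_models(spec)
    transcripts = [tx for m in models for tx in m.transcripts]
    genes = [m.gene_id for m in models for _ in m.transcripts]
    exp_normal = np.concatenate([m.tpm_normal for m in models])
    exp_cancer = np.concatenate([m.tpm_cancer for m in models])

    normal_ids = [f"{spec.cohort}_N{i:03d}" for i in range(1, spec.n_normal + 1)]
    cancer_ids = [f"{spec.cohort}_C{i:03d}" for i in range(1, spec.n_cancer + 1)]

    rng = np.random.default_rng([spec.seed, 1])
    cols = {}
    for sid in normal_ids:
        cols[sid] = _draw_counts(exp_normal, spec, rng)
    for sid in cancer_ids:
        cols[sid] = _draw_counts(exp_cancer, spec, rng)
    counts_df = pd.DataFrame(cols, index=pd.Index(transcripts, name="transcript_id"))

    col_sums = counts_df.sum(axis=0)
    safe = col_sums.replace(0, np.nan)
    tpm_df = (counts_df / safe * 1e6).fillna(0.0)

    counts = ExpressionMatrix(counts_df, kind="counts")
    tpm = ExpressionMatrix(tpm_df, kind="tpm")
    annotation = pd.Series(genes, index=counts_df.index, name="gene_id")
    samples = pd.DataFrame(
        {
            "condition": ["normal"] * len(normal_ids) + ["cancer"] * len(cancer_ids),
            "cohort": spec.cohort,
        },
        index=pd.Index(normal_ids + cancer_ids, name="sample_id"),
    )
    truth = truth.copy()
    truth.insert(0, "cohort", spec.cohort)
    return counts, tpm, annotation, samples, truth


def generate_cohorts(
    spec: ScenarioSpec, cohorts: list[str]
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Generate several cohorts sharing one gene/transcript structure.

    Each cohort reuses the spec's gene models (same planted switches and
    expected values) but draws its own sampling noise, emulating the same
    biology assayed in independent cohorts.
    """
    parts = []
    for ci, name in enumerate(cohorts):
        sub = dataclasses.replace(spec, cohort=name, seed=spec.seed)
        counts_i, tpm_i, ann, samples_i, truth_i = _generate_with_offset(sub, ci)
        parts.append((counts_i, tpm_i, ann, samples_i, truth_i))
    counts = ExpressionMatrix(
        pd.concat([p[0].values for p in parts], axis=1), kind="counts"
    )
    tpm = ExpressionMatrix(pd.concat([p[1].values for p in parts], axis=1), kind="tpm")
    annotation = parts[0][2]
    samples = pd.concat([p[3] for p in parts], axis=0)
    truth = pd.concat([p[4] for p in parts], axis=0, ignore_index=True)
    return counts, tpm, annotation, samples, truth


def _generate_with_offset(spec: ScenarioSpec, cohort_index: int):
    """Like generate_cohort but with a cohort-specific sampling stream."""
    models, truth = build_gene_models(spec)
    transcripts = [tx for m in models for tx in m.transcripts]
    genes = [m.gene_id for m in models for _ in m.transcripts]
    exp_normal = np.concatenate([m.tpm_normal for m in models])
    exp_cancer = np.concatenate([m.tpm_cancer for m in models])
    normal_ids = [f"{spec.cohort}_N{i:03d}" for i in range(1, spec.n_normal + 1)]
    cancer_ids = [f"{spec.cohort}_C{i:03d}" for i in range(1, spec.n_cancer + 1)]
    rng = np.random.default_rng([spec.seed, 1, cohort_index])
    cols = {}
    for sid in normal_ids:
        cols[sid] = _draw_counts(exp_normal, spec, rng)
    for sid in cancer_ids:
        cols[sid] = _draw_counts(exp_cancer, spec, rng)
    counts_df = pd.DataFrame(cols, index=pd.Index(transcripts, name="transcript_id"))
    col_sums = counts_df.sum(axis=0)
    safe = col_sums.replace(0, np.nan)
    tpm_df = (counts_df / safe * 1e6).fillna(0.0)
    counts = ExpressionMatrix(counts_df, kind="counts")
    tpm = ExpressionMatrix(tpm_df, kind="tpm")
    annotation = pd.Series(genes, index=counts_df.index, name="gene_id")
    samples = pd.DataFrame(
        {
            "condition": ["normal"] * len(normal_ids) + ["cancer"] * len(cancer_ids),
            "cohort": spec.cohort,
        },
        index=pd.Index(normal_ids + cancer_ids, name="sample_id"),
    )
    truth = truth.copy()
    truth.insert(0, "cohort", spec.cohort)
    return counts, tpm, annotation, samples, truth


def plant_switches(
    spec: ScenarioSpec,
    n: int,
    expression_class: str = "concordant",
    delta_if: float = 0.3,
    gene_fold: float | None = None,
    start_gene: int = 0,
) -> list[PlantedSwitch]:
    """Convenience: plant ``n`` switches of one class on consecutive genes.

    Transcript pairs are auto-designated (top two baseline-usage isoforms).
    Returns the planted list; the caller assigns it to ``spec.planted``.
    """
    gene_ids = spec.gene_ids()
    if start_gene + n > len(gene_ids):
        raise ValueError("not enough genes to plant the requested switches")
    return [
        PlantedSwitch(
            gene_id=gene_ids[start_gene + i],
            delta_if=delta_if,
            expression_class=expression_class,
            gene_fold=gene_fold,
        )
        for i in range(n)
    ]
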