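# Methods

## Overview

`switchquant` implements a quantitative isoform-switching analysis for
two-condition (normal vs. cancer) transcript-level expression data. The
pipeline has seven stages: usage computation, expression filtering,
differential transcript usage (DTU) testing, differential transcript
expression (DTE) testing, switch identification, switch quantification
(concordance classification and characteristic frequencies), and
prioritization. A synthetic-cohort generator with planted switches closes
the loop for benchmarking.

## Transcript usage and dIF

Usage is computed per sample as the transcript's TPM divided by the summed
TPM of all transcripts of its parent gene. Where the gene's summed TPM is
exactly zero, usage is set to exactly 0 for all of its transcripts; this
zero rule is the only special case, and it guarantees the invariant that
per-gene usages sum to 1 (within 1e-9) or are all zero. dIF is the
difference of the *arithmetic means of per-sample usage ratios* between
conditions — a mean of ratios, not a ratio of means, so every sample
contributes equally regardless of its sequencing depth.

## Expression filtering

Transcripts enter both tests only if they pass a count-based expression
filter, a reimplementation of the default logic of the standard
`filterByExpr` filter: a transcript is kept when its CPM exceeds
`min_count` (default 10) scaled by the median library size in millions, in
at least `n_min` samples, and its total count reaches `min_total`
(default 15). `n_min` is the smaller condition group's size, attenuated
for groups above 10 samples (`n_min = 10 + 0.7 · (min_group − 10)`). The
implementation is verified against `edgeR::filterByExpr` on random
fixtures in the test suite. Filtering is per-cohort by default (each
cohort is tested separately); a pooled mode is available via
`AnalysisConfig.filter_per_cohort = False`. The same kept set feeds DTU
and DTE, so both result tables describe the identical transcript universe.

## DTU and DTE testing

The built-in two-group test is the two-sided Mann–Whitney rank-sum test:
on per-sample usage values for DTU, on per-sample log2(TPM + pseudocount)
for DTE. Numerical choices:

* **Exact enumeration for combined n ≤ 20.** The null distribution is
  enumerated over all group assignments, which handles ties exactly (e.g.
  3 vs 3 with complete separation gives p = 2/20 = 0.1).
* **Tie-corrected normal approximation, without continuity correction,
  otherwise.** For a discrete statistic the continuity correction makes
  p-values systematically conservative; at the scale of a full study
  (thousands of pooled tests) that conservativeness is large enough to be
  detectable as non-uniformity of the null p-value distribution. The
  uncorrected approximation tracks the mid-p of the discrete null and
  keeps pooled null p-values uniform, which matters because the
  Benjamini–Hochberg correction is applied globally over all cohorts'
  p-values at once.
* **p = 1 for jointly constant groups.** A transcript with identical
  values in every sample of both groups carries no information about a
  location shift; the convention avoids undefined statistics on
  degenerate (typically all-zero) synthetic inputs.

Note that p-values of isoforms of the same gene are dependent (usages sum
to one within a gene; in a two-isoform gene the two transcripts have
identical two-sided p-values). Aggregate uniformity checks on pooled DTU
p-values therefore overstate significance slightly; this is inherent to
per-transcript testing of compositional data.

Externally produced DTU or DTE tables (e.g. from quasi-binomial or
negative-binomial quasi-likelihood frameworks) can replace the built-in
tests through `load_external_dtu` / `load_external_dte`; external p-values
and fold changes are taken verbatim, BH re-applied only when the table
lacks adjusted values, and all downstream stages are unchanged.

## Fold changes and DE calls

log2 fold change is `log2(mean cancer TPM + c) − log2(mean normal TPM +
c)` with symmetric pseudocount `c = 0.01` (configurable); the difference-
of-logs form makes fold changes exactly antisymmetric under swapping the
condition labels. The DE call itself is `adj_p < alpha` only — fold-change
magnitude never enters the call, and only supplies the direction label for
transcripts that are called DE.

## Switch identification and classification

Within each gene and cohort, the switch list is the Cartesian product of
significantly up-used and significantly down-used transcripts
(`|dIF| > 0.1`, `adj_p < 0.05` by default). Roles are condition-defined
and pairs are ordered (cancer_tx, normal_tx); a transcript may appear in
several switches. Summary counts are reported at three granularities:
switch events, unique genes, and unique ordered pairs (a pair found in two
cohorts is two events but one unique pair).

The concordance class is read off the two transcripts' DE status and
direction: `concordant` (both DE, expression codirectional with usage),
`reverse` (both DE, both opposite), `both_down` / `both_up` (both DE, same
sign), `cancer_not_de` / `normal_not_de` (exactly one not DE),
`both_not_de` (neither). `both_not_de` and `reverse` are structurally
near-impossible when both usage shifts are genuine — equal expression
changes cannot produce opposite usage changes — so their occurrence is
logged as a warning rather than an error (finite-sample significance can
fail one transcript).

## Characteristic frequencies

`f_cancer` is the proportion of cancer samples in which the cancer
transcript's expression strictly exceeds the normal transcript's;
`f_normal` the proportion of normal samples with the strict reverse order.
Ties count toward neither frequency — measure-zero for continuous
expression but relevant when both transcripts are exactly 0. Because usage
divides both transcripts by the same per-sample gene total, frequencies
computed from TPM and from usage agree exactly whenever the gene is
expressed in every sample; the TPM route is used so that samples with an
unexpressed gene (both usages 0) are handled identically. The ranking
score is the product `f_cancer · f_normal`; the additive legacy score
`f_cancer + f_normal − 1` is reported alongside but conflates (1, 0) with
(0.5, 0.5).

## Prioritization

The filter chain applies, in order: (1) keep concordant switches only;
(2) drop combined frequency exactly 0; (3) optionally require combined
frequency strictly above `min_combined_freq` (0.5 recommended);
(4) optionally require both |log2FC| strictly above `lfc_filter`
(disabled by default — the core chain is class- and frequency-based, and
the fold-change cutoff is an alternative documented for completeness).
Boundary semantics: strict `>` for frequency and fold-change cutoffs,
`≥` for the auxiliary TPM floor. Ranking is by combined frequency
descending with a deterministic lexicographic tie-break (gene, cancer_tx,
normal_tx). Two auxiliary filters reproduce prevalence-reversal
post-processing: a mean-expression floor (both transcripts ≥ 1 TPM in
cancer or in normal samples) and a usage anti-correlation requirement
(Spearman ρ < −0.8 across all cohort samples, both conditions pooled;
undefined ρ drops the switch with a warning).

## Synthetic cohorts

The generator emulates bulk tumor/normal RNA-seq at the transcript level:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 100 | genes per cohort |
| `isoforms_per_gene` | 2–5 | uniform over the range |
| `n_normal`, `n_cancer` | 25 | samples per condition (the design minimum) |
| baseline usage | Dirichlet(α = 2) | avoids degenerate near-0/1 baselines |
| gene abundance | log-normal, ln-mean 4.0, ln-sd 1.0 | median ≈ 55 TPM |
| `dispersion` | 10 | NB size; larger = less noise; `inf` = noise-free |
| `library_size` | 2 × 10⁶ | expected counts per sample |

Planted switches transfer `delta_if` (default 0.3) of usage mass from the
designated normal transcript to the designated cancer transcript in the
cancer condition; other isoforms are untouched, so the pair's expected dIF
is exactly ±delta_if. When the normal transcript's baseline usage is too
small to give away `delta_if`, the shortfall is borrowed proportionally
from the other isoforms before planting. A gene-level fold change places
the pair in one of five expression classes; the not-DE classes solve the
fold exactly (e.g. `cancer_not_de` uses the fold at which the cancer
transcript's expected expression is identical across conditions), and
`both_down` / `both_up` scale it so the flatter transcript moves by
exactly the requested factor.

Counts are negative-binomial (mean = expected TPM × library share, size =
`dispersion`); emitted TPM is recomputed from counts by column
normalization to 10⁶. Because TPM is compositional, a net expected
expression shift of the planted genes would rescale *every* transcript in
the cancer condition and contaminate the planted classes; by default the
generator therefore applies a uniform compensating fold to the unplanted
background genes so expected library composition is equal across
conditions (`balance_composition=True`; a no-op for scenarios whose plants
are composition-neutral, including all-null and all-concordant designs).

All gene-level structure derives from per-gene seeded RNG streams, so
`expected_class` can recompute a planted pair's expectation-implied class
from the scenario alone — an algebraic oracle independent of any generated
cohort — and identical seeds give bit-identical cohorts.

What the generator does **not** model: transcript lengths (treated as
equal, so counts ∝ TPM and no length bias exists), splice-graph structure,
batch effects, sample-specific library-size variation, GC/mappability
bias, and cohort-specific effect-size distributions (multi-cohort
generation reuses one gene structure with independent sampling noise).
Passing benchmarks on these cohorts therefore demonstrates correctness of
the statistical machinery under a well-specified model, not robustness to
real-data artifacts such as length-dependent quantification uncertainty.

## Problem sizes used in validation

The automated checks run null calibrations on 200-gene cohorts at 25/25
samples (20 seeds), detection benchmarks with 50 planted concordant
switches per cohort (10 seeds), and classification benchmarks with 48
planted switches across four classes at 50/50 samples and low noise
(dispersion 100, 3 seeds). These sizes give stable aggregate metrics
(hundreds of planted events per estimate) while keeping a full validation
run in the tens of seconds.

## Known limitations

* The built-in rank tests are distribution-free substitutes for
  model-based DTU/DTE frameworks; they preserve direction and significance
  semantics but not the exact power profile of quasi-likelihood methods.
  The external-table adapters exist precisely so results from those stacks
  can flow through the identical switch logic.
* TPM must be on the linear scale; log-transformed inputs are not
  detected automatically.
* The per-transcript log2 fold change is computed from TPM means with a
  pseudocount, not from a fitted count model; both the pseudocount and the
  choice are configurable/documented rather than inferred.
* Frequencies use strict inequality; cohorts with heavy zero-inflation in
  both transcripts will shrink both sub-frequencies rather than split
  ties.
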