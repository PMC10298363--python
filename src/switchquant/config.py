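"""Analysis configuration shared by all pipeline stages.

The thresholds collected here drive every downstream decision: the minimum
mean usage change (|dIF|) for a transcript to count as up- or down-used, the
FDR level for both the usage and the expression tests, the TPM cutoff that
separates lowly from highly expressed transcripts, and the optional filters
applied during switch prioritization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and switches governing a full analysis run.

    Parameters
    ----------
    dif_threshold:
        Minimum absolute mean change in transcript usage (dIF) for a
        transcript to be called up- or down-used. Default 0.1.
    alpha:
        FDR level applied to globally BH-adjusted p-values of both the
        usage and the expression tests. Default 0.05.
    low_expression_tpm:
        Mean-TPM threshold (in normal samples) separating lowly from highly
        expressed transcripts in the stratified summaries. Default 1 TPM.
    lfc_filter:
        Minimum absolute log2 fold change required of *both* transcripts by
        the optional expression-magnitude stage of the prioritization chain
        (strict ``>``). Only applied when ``lfc_filter_enabled`` is true.
    lfc_filter_enabled:
        The fold-change stage ships disabled: the core chain is class +
        combined-frequency based, with fold-change filtering an opt-in
        alternative.
    min_combined_freq:
        Optional strict lower bound on the combined frequency in the
        prioritization chain; 0 disables the stage (switches with combined
        frequency exactly 0 are always removed by the preceding stage).
    rho_threshold:
        Spearman correlation ceiling for the usage anti-correlation filter;
        switches are kept when the two transcripts' usage vectors correlate
        below this value. Default -0.8.
    pseudocount:
        Symmetric pseudocount added to mean TPM in both conditions before
        taking log2 fold changes. Default 0.01.
    seed:
        Seed for every stochastic component of a run.
    filter_per_cohort:
        Whether the expression filter is evaluated within each cohort
        (default) or once on the pooled samples.
    """

    dif_threshold: float = 0.1
    alpha: float = 0.05
    low_expression_tpm: float = 1.0
    lfc_filter: float = 1.0
    lfc_filter_enabled: bool = False
    min_combined_freq: float = 0.0
    rho_threshold: float = -0.8
    pseudocount: float = 0.01
    seed: int = 0
    filter_per_cohort: bool = True

    def __post_init__(self) -> None:
        if self.dif_threshold <= 0:
            raise ValueError("dif_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.min_combined_freq < 0:
            raise ValueError("min_combined_freq must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
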