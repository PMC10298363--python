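"""Isoform switch identification from DTU results.

Within each gene and cohort, every significantly up-used transcript
("cancer" transcript: dIF above the threshold, adjusted p below alpha) is
paired with every significantly down-used transcript ("normal" transcript)
in a Cartesian product. A transcript may therefore participate in several
switches of the same gene, and roles are condition-defined: pairs are
ordered (cancer_tx, normal_tx), never treated as unordered sets.
"""

from __future__ import annotations

import pandas as pd

from .config import AnalysisConfig

SWITCH_COLUMNS = [
    "gene_id", "cohort", "cancer_tx", "normal_tx", "dIF_cancer", "dIF_normal",
]


def identify_switches(dtu: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """All (up x down) transcript pairs per gene and cohort.

    Output is deterministically ordered by (cohort, gene_id, cancer_tx,
    normal_tx). An empty result is valid.
    """
    required = {"transcript_id", "gene_id", "cohort", "dIF", "adj_p",
                "usage_direction"}
    missing = required - set(dtu.columns)
    if missing:
        raise ValueError(f"DTU table missing columns: {sorted(missing)}")
    up = dtu[dtu["usage_direction"] == "up"]
    down = dtu[dtu["usage_direction"] == "down"]
    merged = up.merge(
        down,
        on=["gene_id", "cohort"],
        suffixes=("_up", "_down"),
    )
    switches = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "cohort": merged["cohort"],
            "cancer_tx": merged["transcript_id_up"],
            "normal_tx": merged["transcript_id_down"],
            "dIF_cancer": merged["dIF_up"],
            "dIF_normal": merged["dIF_down"],
        }
    )
    switches = switches.sort_values(
        ["cohort", "gene_id", "cancer_tx", "normal_tx"], kind="stable"
    ).reset_index(drop=True)
    assert (switches["cancer_tx"] != switches["normal_tx"]).all()
    assert (switches["dIF_cancer"] > config.dif_threshold).all()
    assert (switches["dIF_normal"] < -config.dif_threshold).all()
    return switches[SWITCH_COLUMNS]


def summarize_switches(switches: pd.DataFrame) -> dict:
    """Switch counts at the three granularities: events, genes, ordered pairs.

    A pair found in two cohorts counts as two switches but one unique pair;
    uniqueness keys the ordered (cancer_tx, normal_tx) role assignment.
    """
    per_cohort = switches.groupby("cohort").size().to_dict()
    unique_pairs = switches.drop_duplicates(["gene_id", "cancer_tx", "normal_tx"])
    return {
        "n_switches": int(len(switches)),
        "n_unique_genes": int(switches["gene_id"].nunique()),
        "n_unique_pairs": int(len(unique_pairs)),
        "per_cohort": {str(k): int(v) for k, v in sorted(per_cohort.items())},
    }
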