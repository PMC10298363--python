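"""Domain types and TSV/GTF readers and writers.

All tables are tab-delimited UTF-8 text with a header row. Expression
matrices are stored transcripts-as-rows, samples-as-columns; every join in
the pipeline is keyed by string identifiers, never by position. Missing
values are not allowed anywhere: absence of expression must be written as 0.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from gffutils.iterators import DataIterator

CONDITIONS = ("normal", "cancer")

#: Number of significant digits preserved by the TSV writers; round-trips
#: are exact at this precision.
FLOAT_FORMAT = "%.10g"


class ExpressionMatrix:
    """Non-negative transcripts x samples matrix tagged with its unit.

    Parameters
    ----------
    values:
        DataFrame with transcript ids as index and sample ids as columns.
    kind:
        Either ``"tpm"`` or ``"counts"``.
    """

    def __init__(self, values: pd.DataFrame, kind: str):
        if kind not in ("tpm", "counts"):
            raise ValueError(f"kind must be 'tpm' or 'counts', got {kind!r}")
        _check_unique(values.index, "transcript")
        _check_unique(values.columns, "sample")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_non_numeric(values)
            raise ValueError(f"non-numeric value at {bad}")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at transcript {values.index[r]!r}, "
                f"sample {values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value at transcript {values.index[r]!r}, "
                f"sample {values.columns[c]!r}"
            )
        self.values = values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.values.index.name = "transcript_id"
        self.kind = kind

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.kind == other.kind and self.values.equals(other.values)

    def __repr__(self) -> str:  # pragma: no cover
        n, m = self.shape
        return f"ExpressionMatrix(kind={self.kind!r}, {n} transcripts x {m} samples)"


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


def _first_non_numeric(values: pd.DataFrame) -> str:
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna() & values[col].notna()
        if bad.any():
            row = values.index[bad.to_numpy()][0]
            return f"transcript {row!r}, sample {col!r}"
    return "unknown position"


def read_expression_matrix(path: str | Path, kind: str) -> ExpressionMatrix:
    """Read a TSV with a header of sample ids and a first column of transcript ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    # coerce object columns so we can report coordinates instead of a dtype error
    if any(df[c].dtype == object for c in df.columns):
        bad = _first_non_numeric(df)
        raise ValueError(f"non-numeric value at {bad} in {path}")
    return ExpressionMatrix(df, kind=kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_tx2gene(path: str | Path, format: str | None = None) -> pd.Series:
    """Read a transcript-to-gene map from a two-column TSV or a GTF file.

    Returns a Series indexed by transcript_id with gene_id values. The GTF
    reader looks only at feature-type ``transcript`` lines and requires both
    ``gene_id`` and ``transcript_id`` attributes (GENCODE dialect).
    """
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("tx2gene TSV needs two columns: transcript_id, gene_id")
        pairs = df.iloc[:, :2]
        pairs.columns = ["transcript_id", "gene_id"]
    elif format == "gtf":
        records = []
        for feature in DataIterator(str(path)):
            if feature.featuretype != "transcript":
                continue
            try:
                tx = feature.attributes["transcript_id"][0]
            except KeyError:
                raise ValueError(
                    f"GTF transcript feature without transcript_id at "
                    f"{feature.seqid}:{feature.start}"
                ) from None
            gene = feature.attributes["gene_id"][0]
            records.append((tx, gene))
        pairs = pd.DataFrame(records, columns=["transcript_id", "gene_id"])
    else:
        raise ValueError(f"unknown tx2gene format {format!r}")
    dedup = pairs.drop_duplicates()
    counts = dedup.groupby("transcript_id")["gene_id"].nunique()
    conflicted = counts[counts > 1]
    if len(conflicted):
        raise ValueError(
            f"transcript {conflicted.index[0]!r} maps to multiple genes"
        )
    out = dedup.drop_duplicates("transcript_id").set_index("transcript_id")["gene_id"]
    out.name = "gene_id"
    return out


def write_tx2gene(tx2gene: pd.Series, path: str | Path) -> None:
    tx2gene.rename_axis("transcript_id").rename("gene_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def check_annotation_total(tx2gene: pd.Series, matrix: ExpressionMatrix) -> None:
    """Require every matrix transcript to be covered by the annotation."""
    missing = set(matrix.transcript_ids) - set(tx2gene.index)
    if missing:
        example = sorted(missing)[0]
        raise ValueError(
            f"{len(missing)} matrix transcripts missing from annotation, "
            f"e.g. {example!r}"
        )


def read_sample_sheet(path: str | Path, min_per_condition: int = 25) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample_id, condition, cohort.

    Condition strings are normalized case-insensitively to ``normal`` /
    ``cancer``. Cohorts with fewer than ``min_per_condition`` samples in
    either condition trigger a warning (small groups weaken the rank tests),
    but only a cohort entirely missing a condition is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("no samples in sample sheet")
    df = df[["sample_id", "condition", "cohort"]].copy()
    df["condition"] = df["condition"].str.lower()
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        raise ValueError(
            f"unknown condition {df.loc[bad, 'condition'].iloc[0]!r}; "
            f"allowed values: {list(CONDITIONS)}"
        )
    _check_unique(pd.Index(df["sample_id"]), "sample")
    sheet = df.set_index("sample_id")
    validate_sample_sheet(sheet, min_per_condition=min_per_condition)
    return sheet


def validate_sample_sheet(sheet: pd.DataFrame, min_per_condition: int = 25) -> None:
    for cohort, sub in sheet.groupby("cohort"):
        counts = sub["condition"].value_counts()
        for cond in CONDITIONS:
            n = int(counts.get(cond, 0))
            if n == 0:
                raise ValueError(f"cohort {cohort!r} has no {cond} samples")
            if n < min_per_condition:
                warnings.warn(
                    f"cohort {cohort!r} has only {n} {cond} samples "
                    f"(fewer than {min_per_condition})",
                    stacklevel=2,
                )


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def align_inputs(
    tpm: ExpressionMatrix,
    counts: ExpressionMatrix,
    tx2gene: pd.Series,
    samples: pd.DataFrame,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Validate that TPM and counts share keys and join the sample sheet.

    TPM and count matrices must have identical transcript and sample keys
    (order-insensitive; counts are re-ordered to match TPM). Samples listed
    in the sheet but absent from the matrices are dropped with a warning;
    matrix samples absent from the sheet are ignored.
    """
    if set(tpm.transcript_ids) != set(counts.transcript_ids):
        raise ValueError("TPM and count matrices have different transcript sets")
    if set(tpm.sample_ids) != set(counts.sample_ids):
        raise ValueError("TPM and count matrices have different sample sets")
    counts = ExpressionMatrix(
        counts.values.loc[tpm.transcript_ids, tpm.sample_ids], kind=counts.kind
    )
    check_annotation_total(tx2gene, tpm)
    present = samples.index.isin(tpm.sample_ids)
    if not present.all():
        dropped = list(samples.index[~present])
        warnings.warn(
            f"{len(dropped)} sheet samples absent from matrices, e.g. "
            f"{dropped[0]!r}; dropped",
            stacklevel=2,
        )
        samples = samples.loc[present]
    if len(samples) == 0:
        raise ValueError("no overlap between sample sheet and matrices")
    return tpm, counts, tx2gene, samples


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table with the package-wide float format."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
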