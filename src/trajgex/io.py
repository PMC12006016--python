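"""TSV readers and writers for the pipeline's tables.

All tables are tab-separated UTF-8 text with Unix newlines and a header
row; floats are written with 12 significant digits so a write/read round
trip reproduces values to full practical precision.  Genomic coordinates
are 1-based and inclusive throughout.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "read_annotation",
    "write_annotation",
    "read_truth",
    "write_truth",
    "read_table",
    "write_table",
]

_FLOAT_FMT = "%.12g"

SAMPLE_COLUMNS = ["subject_id", "age_months", "sex", "season", "hla"]
ANNOTATION_COLUMNS = ["chrom", "start", "end", "is_t1d", "is_mhc"]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()[:10]
        raise ValueError(f"duplicated {what} identifiers: {dups}")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, lineterminator="\n")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_expression(expression: pd.DataFrame, path) -> None:
    write_table(expression, path)


def read_expression(path) -> pd.DataFrame:
    df = read_table(path)
    df.index.name = "gene_id"
    df.columns.name = "sample_id"
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    write_table(samples, path)


def read_samples(path) -> pd.DataFrame:
    df = read_table(path)
    df.index.name = "sample_id"
    _check_unique(df.index, "sample")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table lacks columns: {missing}")
    df["age_months"] = df["age_months"].astype(float)
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    write_table(annotation, path)


def read_annotation(path) -> pd.DataFrame:
    df = read_table(path)
    df.index.name = "gene_id"
    _check_unique(df.index, "gene")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns: {missing}")
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    write_table(truth, path)


def read_truth(path) -> pd.DataFrame:
    # keep_default_na: the NULL archetype label must not be parsed as NaN
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, na_values=[""])
    df.index.name = "gene_id"
    _check_unique(df.index, "gene")
    if "amplitude_log2" in df.columns:
        df["amplitude_log2"] = df["amplitude_log2"].astype(float)
    return df


def check_sample_alignment(expression: pd.DataFrame, samples: pd.DataFrame) -> None:
    """Every expression column must have a metadata row."""
    missing = expression.columns.difference(samples.index)
    if len(missing):
        raise ValueError(
            f"metadata missing for samples: {sorted(missing)[:10]}"
        )
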