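"""Reading, validation and harmonisation of gene-by-sample count matrices.

Count matrices are plain pandas DataFrames with gene identifiers as the
index and sample identifiers as columns.  Values are non-negative reals;
fractional counts are permitted (multimapping reads may be assigned
fractionally upstream).  Sample metadata travel as a DataFrame with one row
per sample (columns: sample_id, cohort, subgroup, replicate_group,
excluded), mirroring the TSV layout used on disk.

Gene identifiers are matched as exact strings; no symbol/ID mapping is
attempted.  Missing values are rejected: every downstream formula assumes
complete columns.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

COHORTS = ("patient", "cell_line")
SUBGROUPS = ("HRD1", "HRD0", "NA")
ANNOTATION_COLUMNS = ("sample_id", "cohort", "subgroup", "replicate_group", "excluded")


def _duplicates(values: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen.add(v)
    return dups


def validate_count_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check count-matrix invariants, returning the matrix unchanged.

    Raises
    ------
    ValidationError
        On duplicate gene/sample identifiers, negative values, or missing
        values.
    """
    gene_dups = _duplicates(matrix.index.astype(str))
    if gene_dups:
        raise ValidationError(f"duplicate gene identifiers: {gene_dups}")
    sample_dups = _duplicates(matrix.columns.astype(str))
    if sample_dups:
        raise ValidationError(f"duplicate sample identifiers: {sample_dups}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("count matrix contains non-numeric values")
    nan_mask = np.isnan(values)
    if nan_mask.any():
        i, j = np.argwhere(nan_mask)[0]
        raise ValidationError(
            f"missing value at gene {matrix.index[i]!r}, sample {matrix.columns[j]!r}"
        )
    neg_mask = values < 0
    if neg_mask.any():
        i, j = np.argwhere(neg_mask)[0]
        raise ValidationError(
            f"negative value {values[i, j]} at gene {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r}"
        )
    return matrix


def read_count_matrix(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a delimited gene-by-sample matrix.

    The first column holds gene identifiers and the header row holds sample
    identifiers.  Input gene order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        matrix = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    except ValueError as exc:  # pandas reports the offending line in its message
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    matrix.index = matrix.index.astype(str)
    matrix.index.name = None  # round trips compare equal to in-memory matrices
    matrix.columns = matrix.columns.astype(str)
    non_numeric = [c for c in matrix.columns if not np.issubdtype(matrix[c].dtype, np.number)]
    if non_numeric:
        for col in non_numeric:
            bad = matrix[pd.to_numeric(matrix[col], errors="coerce").isna()]
            line = matrix.index.get_loc(bad.index[0]) + 2  # +1 header, +1 one-based
            raise ValidationError(
                f"non-numeric value in sample {col!r} at line {line} of {path}"
            )
    return validate_count_matrix(matrix.astype(float))


def write_count_matrix(matrix: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    """Write a matrix with a mandatory header row, UTF-8, '.' decimal."""
    pd.DataFrame(matrix).to_csv(path, sep=delimiter, index_label="gene_id", encoding="utf-8")


def read_annotation(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a sample-metadata table and validate its invariants."""
    table = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"annotation table missing columns: {missing}")
    table["excluded"] = table["excluded"].str.lower().map(
        {"true": True, "false": False, "1": True, "0": False}
    )
    if table["excluded"].isna().any():
        raise ValidationError("excluded column must be boolean (true/false)")
    return validate_annotation(table)


def validate_annotation(table: pd.DataFrame) -> pd.DataFrame:
    dups = _duplicates(table["sample_id"])
    if dups:
        raise ValidationError(f"duplicate annotated sample_ids: {dups}")
    bad_cohort = sorted(set(table["cohort"]) - set(COHORTS))
    if bad_cohort:
        raise ValidationError(f"unknown cohort labels: {bad_cohort}")
    bad_sub = sorted(set(table["subgroup"].fillna("NA")) - set(SUBGROUPS))
    if bad_sub:
        raise ValidationError(f"unknown subgroup labels: {bad_sub}")
    labelled_lines = table[
        (table["cohort"] == "cell_line") & (table["subgroup"].fillna("NA") != "NA")
    ]
    if len(labelled_lines):
        raise ValidationError(
            "subgroup labels are only valid for patient samples; offending: "
            f"{list(labelled_lines['sample_id'])}"
        )
    return table


def write_annotation(table: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    table.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def merge_on_shared_genes(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Merge matrices on the intersection of their gene sets.

    Gene order follows the first table; samples are concatenated in input
    order.  Sample identifier sets must be pairwise disjoint.
    """
    if len(tables) < 2:
        raise ValidationError("merge requires at least two tables")
    seen_samples: set[str] = set()
    collisions: list[str] = []
    for t in tables:
        overlap = seen_samples & set(t.columns)
        collisions.extend(sorted(overlap))
        seen_samples |= set(t.columns)
    if collisions:
        raise ValidationError(f"sample identifiers collide across tables: {collisions}")
    shared = set(tables[0].index)
    for t in tables[1:]:
        shared &= set(t.index)
    if not shared:
        raise ValidationError("no genes shared by all tables")
    genes = [g for g in tables[0].index if g in shared]
    merged = pd.concat([t.loc[genes] for t in tables], axis=1)
    return validate_count_matrix(merged)


def apply_sample_filters(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    keep_suffix: str | None = None,
) -> pd.DataFrame:
    """Drop excluded samples; optionally keep only patients with a given id suffix.

    Cell-line samples are never affected by the suffix filter.  Values of
    retained columns are untouched.
    """
    ann = annotation.set_index("sample_id")
    unannotated = [s for s in matrix.columns if s not in ann.index]
    if unannotated:
        raise ValidationError(f"samples without annotation: {unannotated}")
    # metadata tables routinely cover more samples than the expression data;
    # annotated-but-absent samples are dropped with a warning, not an error
    absent = [s for s in ann.index if s not in matrix.columns]
    if absent:
        warnings.warn(
            f"{len(absent)} annotated sample(s) absent from the count matrix "
            f"(first: {absent[0]})",
            stacklevel=2,
        )
    keep: list[str] = []
    for s in matrix.columns:
        row = ann.loc[s]
        if bool(row["excluded"]):
            continue
        if keep_suffix is not None and row["cohort"] == "patient" and not s.endswith(keep_suffix):
            continue
        keep.append(s)
    return matrix[keep]


def cpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: scale every column to sum to 1e6."""
    sums = matrix.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(f"zero-sum sample columns: {list(zero.index)}")
    return matrix / sums * 1e6
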