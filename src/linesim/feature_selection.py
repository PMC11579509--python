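"""Expression filtering and frozen most-variable-gene selection.

Selections are built on a reference table and then applied, frozen, to an
extended table: appended samples can never influence which genes are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class GeneSelection:
    """An ordered, frozen list of gene identifiers with its provenance."""

    selected_gene_ids: tuple[str, ...]
    criterion: str  # "cpm_filter" | "iqr_top_k"
    parameters: dict = field(default_factory=dict)
    source_table_id: str = ""

    def __post_init__(self):
        if len(set(self.selected_gene_ids)) != len(self.selected_gene_ids):
            raise ValidationError("gene selection contains duplicates")

    def __len__(self) -> int:
        return len(self.selected_gene_ids)


def expression_filter(
    matrix_cpm: pd.DataFrame,
    threshold: float = 1.0,
    min_samples: int = 2,
    source_table_id: str = "",
) -> GeneSelection:
    """Keep genes with CPM strictly above `threshold` in >= `min_samples` samples.

    Input gene order is preserved.
    """
    if min_samples > matrix_cpm.shape[1]:
        raise ValidationError(
            f"min_samples={min_samples} exceeds the {matrix_cpm.shape[1]} available samples"
        )
    hits = (np.asarray(matrix_cpm) > threshold).sum(axis=1)
    selected = tuple(matrix_cpm.index[hits >= min_samples])
    return GeneSelection(
        selected,
        criterion="cpm_filter",
        parameters={"threshold": threshold, "min_samples": min_samples},
        source_table_id=source_table_id,
    )


def gene_iqr(matrix: pd.DataFrame) -> pd.Series:
    """Per-gene interquartile range across samples (linear-interpolation quartiles)."""
    q1, q3 = np.percentile(np.asarray(matrix, dtype=float), [25, 75], axis=1, method="linear")
    return pd.Series(q3 - q1, index=matrix.index, name="iqr")


def top_variable_genes(
    matrix: pd.DataFrame, k: int = 5000, source_table_id: str = ""
) -> GeneSelection:
    """Select the k genes with the largest IQR across samples.

    Ties at the cutoff are broken by input gene order, making the selection
    bit-reproducible.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if matrix.shape[1] < 2:
        raise ValidationError("IQR selection needs at least 2 samples")
    iqr = gene_iqr(matrix).to_numpy()
    # stable sort on the negated statistic leaves ties in input order
    order = np.argsort(-iqr, kind="stable")[: min(k, len(iqr))]
    selected = tuple(matrix.index[order])
    return GeneSelection(
        selected,
        criterion="iqr_top_k",
        parameters={"k": k},
        source_table_id=source_table_id,
    )


def apply_selection(matrix: pd.DataFrame, selection: GeneSelection) -> pd.DataFrame:
    """Row-subset a matrix to the selection, in selection order, values unchanged."""
    missing = [g for g in selection.selected_gene_ids if g not in matrix.index]
    if missing:
        raise ValidationError(f"selected genes absent from matrix: {missing}")
    return matrix.loc[list(selection.selected_gene_ids)]
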