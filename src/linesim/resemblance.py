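"""Spearman correlation profiling of cell lines against patient tumors.

A correlation profile is a cell-line-by-patient DataFrame of Spearman rank
correlations computed over a frozen gene selection.  Profiles are averaged
over technical replicates, summarised per cell line (mean or median across
patients), ranked, and contrasted between hyperdiploid (HRD1) and
non-hyperdiploid (HRD0) patient subgroups.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .feature_selection import GeneSelection, apply_selection

RANKING_COLUMNS = [
    "cell_line",
    "summary_rho",
    "rank_all",
    "mean_rho_HRD1",
    "mean_rho_HRD0",
    "delta_rho",
    "rank_HRD1",
    "rank_HRD0",
]


def _rank_columns(matrix: pd.DataFrame, label: str) -> np.ndarray:
    """Average-rank each sample column; error on zero rank variance."""
    values = np.asarray(matrix, dtype=float)
    ranks = np.apply_along_axis(rankdata, 0, values)  # average ranks with ties
    sd = ranks.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValidationError(
            f"{label} sample(s) constant over the selected genes, Spearman rho "
            f"undefined: {list(matrix.columns[flat])}"
        )
    return (ranks - ranks.mean(axis=0)) / sd


def spearman_profile(
    cell_lines: pd.DataFrame,
    patients: pd.DataFrame,
    genes: GeneSelection,
) -> pd.DataFrame:
    """Spearman rho for every (cell line, patient) pair over the selected genes.

    Ties receive average ranks, so rho equals the Pearson correlation of the
    rank vectors.
    """
    if len(genes) < 3:
        raise ValidationError("Spearman profiling needs at least 3 selected genes")
    cells = apply_selection(cell_lines, genes)
    pats = apply_selection(patients, genes)
    zc = _rank_columns(cells, "cell line")
    zp = _rank_columns(pats, "patient")
    rho = zc.T @ zp / zc.shape[0]
    return pd.DataFrame(rho, index=cells.columns, columns=pats.columns)


def average_replicates(
    profile: pd.DataFrame, replicate_map: Mapping[str, str]
) -> pd.DataFrame:
    """Average profile rows over replicate groups (one output row per group).

    Group order follows first appearance among the profile's cell lines.
    """
    unknown = [c for c in replicate_map if c not in profile.index]
    if unknown:
        raise ValidationError(f"replicate map references unknown cell lines: {unknown}")
    unmapped = [c for c in profile.index if c not in replicate_map]
    if unmapped:
        raise ValidationError(f"cell lines without a replicate group: {unmapped}")
    groups = pd.Series({c: replicate_map[c] for c in profile.index}, name="group")
    order = list(dict.fromkeys(groups.loc[profile.index]))
    averaged = profile.groupby(groups, sort=False).mean()
    return averaged.loc[order]


def summarize_and_rank(
    profile: pd.DataFrame,
    summary: str = "mean",
    patient_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Summarise each cell line over a patient subset and rank (1 = most similar).

    Ties in the summary share order by cell-line identifier, deterministically.
    """
    if summary not in ("mean", "median"):
        raise ValidationError(f"unknown summary statistic: {summary!r}")
    if patient_subset is None:
        subset = profile
    else:
        missing = [p for p in patient_subset if p not in profile.columns]
        if missing:
            raise ValidationError(f"patients absent from profile: {missing}")
        if not patient_subset:
            raise ValidationError("patient subset is empty")
        subset = profile[list(patient_subset)]
    stat = subset.mean(axis=1) if summary == "mean" else subset.median(axis=1)
    table = pd.DataFrame({"cell_line": profile.index, "summary_rho": stat.to_numpy()})
    table = table.sort_values(
        ["summary_rho", "cell_line"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank_all"] = np.arange(1, len(table) + 1)
    return table


def _ranks_of(values: pd.Series) -> pd.Series:
    """Dense 1..n ranks, largest first, ties broken by index identifier."""
    order = sorted(values.index, key=lambda c: (-values[c], c))
    return pd.Series({c: i + 1 for i, c in enumerate(order)})


def subgroup_contrast(
    profile: pd.DataFrame,
    annotation: pd.DataFrame,
    summary: str = "mean",
) -> pd.DataFrame:
    """Per-line HRD1/HRD0 mean correlations, their difference, and ranks.

    Requires every profile patient to carry an HRD1 or HRD0 label and both
    groups to be non-empty.  delta_rho = mean_rho_HRD1 - mean_rho_HRD0.
    """
    ann = annotation.set_index("sample_id")
    labels = {}
    for p in profile.columns:
        if p not in ann.index:
            raise ValidationError(f"patient {p!r} not annotated")
        sub = ann.loc[p, "subgroup"]
        if sub not in ("HRD1", "HRD0"):
            raise ValidationError(f"patient {p!r} lacks an HRD1/HRD0 label")
        labels[p] = sub
    hrd1 = [p for p, s in labels.items() if s == "HRD1"]
    hrd0 = [p for p, s in labels.items() if s == "HRD0"]
    if not hrd1 or not hrd0:
        raise ValidationError("both HRD1 and HRD0 patient groups must be non-empty")

    overall = summarize_and_rank(profile, summary=summary).set_index("cell_line")
    mean1 = profile[hrd1].mean(axis=1)
    mean0 = profile[hrd0].mean(axis=1)
    table = pd.DataFrame(
        {
            "cell_line": profile.index,
            "summary_rho": overall.loc[profile.index, "summary_rho"].to_numpy(),
            "rank_all": overall.loc[profile.index, "rank_all"].to_numpy(),
            "mean_rho_HRD1": mean1.to_numpy(),
            "mean_rho_HRD0": mean0.to_numpy(),
        }
    )
    table["delta_rho"] = table["mean_rho_HRD1"] - table["mean_rho_HRD0"]
    rank1 = _ranks_of(mean1)
    rank0 = _ranks_of(mean0)
    table["rank_HRD1"] = [rank1[c] for c in table["cell_line"]]
    table["rank_HRD0"] = [rank0[c] for c in table["cell_line"]]
    table["rank_shift"] = table["rank_all"] - table["rank_HRD1"]
    return table
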