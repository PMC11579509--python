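"""Concordance between cell-surface protein intensity (gMFI) and mRNA (TPM).

Each marker is measured per cell line both by flow cytometry (geometric
mean fluorescence intensity) and by RNA-seq (transcripts per million).
Concordance is the squared Pearson correlation of log10(gMFI) against
log10(TPM) across cell lines, reflecting that both axes are examined on a
logarithmic scale.  Zeros are excluded by default (a zero gMFI is a
qualitatively different "absent protein" observation, not a point on the
log axis); a pseudocount policy is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

MIN_PAIRS = 3


@dataclass
class MarkerRecord:
    """One surface marker with per-cell-line (gMFI, TPM) pairs."""

    marker_name: str
    gene_symbol: str
    cell_lines: list[str]
    gmfi: np.ndarray  # fluorescence intensity units, >= 0
    tpm: np.ndarray  # transcripts per million, >= 0
    r_squared: float | None = None
    n_used: int = 0

    def __post_init__(self):
        self.gmfi = np.asarray(self.gmfi, dtype=float)
        self.tpm = np.asarray(self.tpm, dtype=float)
        if (self.gmfi < 0).any() or (self.tpm < 0).any():
            raise ValidationError(f"marker {self.marker_name}: negative gMFI or TPM")
        if not (len(self.cell_lines) == len(self.gmfi) == len(self.tpm)):
            raise ValidationError(f"marker {self.marker_name}: ragged measurement vectors")


def marker_r2(
    record: MarkerRecord,
    zero_policy: str = "exclude",
    pseudocount: float = 1.0,
    log_scale: bool = True,
) -> float | None:
    """Squared Pearson correlation of log10(gMFI) vs log10(TPM) across lines.

    zero_policy="exclude" drops pairs where either value is zero;
    "pseudocount" adds `pseudocount` to both before the log.  Returns None
    (and leaves the record flagged undefined) when fewer than 3 usable pairs
    remain — never silently 0.
    """
    if zero_policy not in ("exclude", "pseudocount"):
        raise ValidationError(f"unknown zero policy: {zero_policy!r}")
    g, t = record.gmfi, record.tpm
    if zero_policy == "exclude":
        usable = (g > 0) & (t > 0)
        g, t = g[usable], t[usable]
    else:
        g, t = g + pseudocount, t + pseudocount
    record.n_used = int(len(g))
    if record.n_used < MIN_PAIRS:
        record.r_squared = None
        return None
    x, y = (np.log10(t), np.log10(g)) if log_scale else (t, g)
    if x.std() == 0 or y.std() == 0:
        record.r_squared = None
        return None
    r = np.corrcoef(x, y)[0, 1]
    record.r_squared = float(r**2)
    return record.r_squared


def concordance_summary(
    records: list[MarkerRecord],
    zero_policy: str = "exclude",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-marker R², n_used, median gMFI and median TPM, plus the panel median R².

    The panel median over defined R² values is stored in ``table.attrs["median_r2"]``.
    """
    if not records:
        raise ValidationError("no marker records given")
    rows = []
    for rec in records:
        r2 = marker_r2(rec, zero_policy=zero_policy, pseudocount=pseudocount)
        rows.append(
            {
                "marker": rec.marker_name,
                "gene": rec.gene_symbol,
                "r_squared": r2,
                "n_used": rec.n_used,
                "median_gmfi": float(np.median(rec.gmfi)),
                "median_tpm": float(np.median(rec.tpm)),
            }
        )
    table = pd.DataFrame(rows)
    defined = table["r_squared"].dropna()
    if defined.empty:
        raise ValidationError("R² undefined for every marker (too few usable pairs)")
    table.attrs["median_r2"] = float(defined.median())
    return table


def read_marker_table(path: str | Path, delimiter: str = "\t") -> list[MarkerRecord]:
    """Read a long-format marker table (columns: marker, gene, cell_line, gmfi, tpm)."""
    table = pd.read_csv(path, sep=delimiter, header=0)
    required = ["marker", "gene", "cell_line", "gmfi", "tpm"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"marker table missing columns: {missing}")
    if table.empty:
        raise ValidationError("marker table has no rows")
    bad = table[table[["gmfi", "tpm"]].isna().any(axis=1)]
    if len(bad):
        raise ValidationError(
            f"non-numeric or missing gmfi/tpm at rows {list(bad.index + 2)}"
        )
    records = []
    for (marker, gene), grp in table.groupby(["marker", "gene"], sort=False):
        records.append(
            MarkerRecord(
                marker_name=str(marker),
                gene_symbol=str(gene),
                cell_lines=[str(c) for c in grp["cell_line"]],
                gmfi=grp["gmfi"].to_numpy(dtype=float),
                tpm=grp["tpm"].to_numpy(dtype=float),
            )
        )
    return records


def marker_records_to_frame(records: list[MarkerRecord]) -> pd.DataFrame:
    """Long-format DataFrame (marker, gene, cell_line, gmfi, tpm) from records."""
    rows = []
    for rec in records:
        for line, g, t in zip(rec.cell_lines, rec.gmfi, rec.tpm):
            rows.append(
                {"marker": rec.marker_name, "gene": rec.gene_symbol,
                 "cell_line": line, "gmfi": g, "tpm": t}
            )
    return pd.DataFrame(rows)
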