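"""Seeded generator of patient/cell-line count data and marker tables.

The generator emulates the statistical structure the resemblance analysis
assumes: a patient cohort split into hyperdiploid (HRD1) and
non-hyperdiploid (HRD0) subgroups that differ in a set of signature genes;
cell lines whose expression profile blends the cohort profile (with a
tunable subgroup tilt) with an independent random profile; two technical
replicates per cell line; and negative-binomial counts whose dispersion
follows the parametric trend alpha(mu) = a0 + a1/mu, the same mean/variance
parameterization (variance = mu + alpha*mu^2) the VST module inverts.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .marker_concordance import MarkerRecord

LN2 = np.log(2.0)


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Log-scale parameters are on the natural-log scale unless the name says
    log2.  ``resemblance`` in [0, 1] is the weight of the cohort profile in
    each cell line's mean profile; ``subgroup_affinity`` in [-1, 1] tilts
    that cohort profile toward HRD1 (+1) or HRD0 (-1).
    """

    n_genes: int = 5000
    n_patients: int = 200
    subgroup_fraction: float = 0.57  # HRD1 share, as in newly-diagnosed cohorts
    n_signature_genes: int = 250
    signature_log2fc: float = 1.0
    baseline_logmean_distribution: tuple[float, float] = (1.0, 2.0)  # mean, sd (natural log)
    trend: tuple[float, float] = (0.05, 2.0)  # (a0, a1)
    library_size_range: tuple[float, float] = (1e6, 2e6)
    n_cell_lines: int = 5
    resemblance: Sequence[float] = (0.95, 0.8, 0.6, 0.4, 0.2)
    subgroup_affinity: Sequence[float] = (0.0, 0.0, 0.0, 0.0, 0.0)
    n_replicates: int = 2
    replicate_noise_sd: float = 0.1
    patient_noise_sd: float = 0.3
    seed: int | None = None

    def validate(self) -> "CohortConfig":
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if not (0 <= self.subgroup_fraction <= 1):
            raise ValidationError("subgroup_fraction must be in [0, 1]")
        a0, a1 = self.trend
        if not (a0 > 0 and a1 >= 0):
            raise ValidationError("trend requires a0 > 0 and a1 >= 0")
        if len(self.resemblance) != self.n_cell_lines:
            raise ValidationError("resemblance must list one value per cell line")
        if len(self.subgroup_affinity) != self.n_cell_lines:
            raise ValidationError("subgroup_affinity must list one value per cell line")
        if any(not 0 <= r <= 1 for r in self.resemblance):
            raise ValidationError("resemblance values must be in [0, 1]")
        if any(not -1 <= a <= 1 for a in self.subgroup_affinity):
            raise ValidationError("subgroup_affinity values must be in [-1, 1]")
        if self.n_signature_genes > self.n_genes:
            raise ValidationError("n_signature_genes exceeds n_genes")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValidationError("library_size_range must be positive and ordered")
        if self.n_replicates < 1 or self.n_patients < 2 or self.n_genes < 1:
            raise ValidationError("cohort dimensions out of range")
        return self


@dataclass
class TruthTable:
    """Planted ground truth accompanying a simulated dataset."""

    line_resemblance: dict = field(default_factory=dict)
    line_affinity: dict = field(default_factory=dict)
    signature_genes: list = field(default_factory=list)
    signature_log2fc: float = 0.0
    gene_log_mean: np.ndarray | None = None  # baseline, natural-log scale
    trend: tuple[float, float] = (0.0, 0.0)
    marker_concordant: dict = field(default_factory=dict)
    marker_slope: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if d["gene_log_mean"] is not None:
            d["gene_log_mean"] = [float(x) for x in d["gene_log_mean"]]
        return d


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """Negative-binomial draw with variance mu + (a0 + a1/mu) * mu^2."""
    mu = np.maximum(mu, 1e-12)
    alpha = a0 + a1 / mu
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p).astype(float)


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate counts, sample annotation and truth for one cohort.

    Returns a gene-by-sample count matrix covering patients and cell-line
    replicates, a sample annotation table, and the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, P = config.n_genes, config.n_patients
    a0, a1 = config.trend

    genes = [f"G{i:05d}" for i in range(G)]
    base_mu, base_sd = config.baseline_logmean_distribution
    log_mean = rng.normal(base_mu, base_sd, size=G)

    sig_idx = rng.choice(G, size=config.n_signature_genes, replace=False)
    sig_shift = np.zeros(G)
    sig_shift[sig_idx] = config.signature_log2fc * LN2

    n_hrd1 = int(round(config.subgroup_fraction * P))
    subgroups = np.array(["HRD1"] * n_hrd1 + ["HRD0"] * (P - n_hrd1))

    # subgroup mean log-profiles; lines blend these according to affinity
    log_hrd1 = log_mean + sig_shift
    log_hrd0 = log_mean

    columns: dict[str, np.ndarray] = {}
    ann_rows = []
    for j in range(P):
        sample = f"P{j:04d}_1_BM"
        profile = (log_hrd1 if subgroups[j] == "HRD1" else log_hrd0) + rng.normal(
            0.0, config.patient_noise_sd, size=G
        )
        rel = np.exp(profile)
        lib = rng.uniform(*config.library_size_range)
        mu = rel / rel.sum() * lib
        columns[sample] = _nb_counts(rng, mu, a0, a1)
        ann_rows.append(
            {"sample_id": sample, "cohort": "patient", "subgroup": subgroups[j],
             "replicate_group": sample, "excluded": False}
        )

    truth = TruthTable(
        signature_genes=[genes[i] for i in sorted(sig_idx)],
        signature_log2fc=config.signature_log2fc,
        gene_log_mean=log_mean,
        trend=(a0, a1),
    )
    for ell in range(config.n_cell_lines):
        name = f"CL{ell:02d}"
        r = float(config.resemblance[ell])
        a = float(config.subgroup_affinity[ell])
        truth.line_resemblance[name] = r
        truth.line_affinity[name] = a
        w1 = (1.0 + a) / 2.0  # weight of the HRD1 profile in the blend
        blend = w1 * log_hrd1 + (1.0 - w1) * log_hrd0
        independent = rng.normal(base_mu, base_sd, size=G)
        line_profile = r * blend + (1.0 - r) * independent
        for rep in range(1, config.n_replicates + 1):
            sample = f"{name}_rep{rep}"
            profile = line_profile + (
                rng.normal(0.0, config.replicate_noise_sd, size=G)
                if config.replicate_noise_sd > 0
                else 0.0
            )
            rel = np.exp(profile)
            lib = rng.uniform(*config.library_size_range)
            mu = rel / rel.sum() * lib
            columns[sample] = _nb_counts(rng, mu, a0, a1)
            ann_rows.append(
                {"sample_id": sample, "cohort": "cell_line", "subgroup": "NA",
                 "replicate_group": name, "excluded": False}
            )

    counts = pd.DataFrame(columns, index=genes)
    annotation = pd.DataFrame(ann_rows)
    return counts, annotation, truth


def simulate_marker_table(
    n_markers: int,
    n_lines: int,
    slope_range: tuple[float, float] = (0.6, 1.2),
    noise_sd: float = 0.1,
    discordant_fraction: float = 0.0,
    zero_fraction: float = 0.0,
    seed: int | None = None,
) -> tuple[list[MarkerRecord], TruthTable]:
    """Simulate a per-marker (gMFI, TPM) panel across cell lines.

    Concordant markers satisfy log10(gmfi) = intercept + slope*log10(tpm) +
    noise; discordant markers draw gMFI independently of TPM.  A
    ``zero_fraction`` of (marker, line) pairs is zeroed in gMFI to exercise
    the zero policy.
    """
    if seed is None:
        raise ValidationError("seed is mandatory")
    if n_lines < 3:
        raise ValidationError("need at least 3 cell lines")
    if not (0 <= discordant_fraction <= 1) or not (0 <= zero_fraction <= 1):
        raise ValidationError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lines = [f"CL{ell:02d}" for ell in range(n_lines)]
    n_discordant = int(round(discordant_fraction * n_markers))
    records: list[MarkerRecord] = []
    truth = TruthTable()
    for m in range(n_markers):
        name = f"M{m:03d}"
        discordant = m < n_discordant
        log_tpm = rng.normal(1.2, 0.6, size=n_lines)  # TPM spread over ~2 decades
        tpm = 10.0**log_tpm
        if discordant:
            slope = 0.0
            log_gmfi = rng.normal(2.0, 0.6, size=n_lines)
        else:
            slope = rng.uniform(*slope_range)
            intercept = rng.uniform(0.5, 1.5)
            log_gmfi = intercept + slope * log_tpm + rng.normal(0.0, noise_sd, size=n_lines)
        gmfi = 10.0**log_gmfi
        if zero_fraction > 0:
            gmfi[rng.random(n_lines) < zero_fraction] = 0.0
        records.append(MarkerRecord(name, f"GENE_{name}", list(lines), gmfi, tpm))
        truth.marker_concordant[name] = not discordant
        truth.marker_slope[name] = float(slope)
    return records, truth
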