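"""End-to-end resemblance pipeline over two merged tables.

The procedure mirrors a two-table design: a reference table (patients plus,
optionally, an external cell-line panel) on which the variance-stabilizing
transformation is fitted and the most-variable genes are frozen, and a
combined table additionally carrying the in-house cell lines on which the
Spearman profiles are computed.  Freezing the gene selection on the
reference table guarantees the appended samples cannot influence which
genes drive the correlations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import counts_io, feature_selection, resemblance, vst
from .errors import LinesimError, StageError, ValidationError
from .marker_concordance import concordance_summary, read_marker_table

logger = logging.getLogger("linesim")


@dataclass
class RunConfig:
    """All parameters of one resemblance run."""

    patient_counts: str
    inhouse_cell_counts: str
    metadata: str
    external_cell_counts: str | None = None
    cpm_threshold: float = 1.0
    cpm_min_samples: int = 2
    top_k: int = 5000
    summary: str = "mean"
    patient_suffix: str | None = None
    exclude_cell_lines: list[str] = field(default_factory=list)
    reference: str = "patients_external"  # or "patients_only"
    seed: int = 0
    outdir: str = "linesim_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        try:
            config = cls(**raw)
        except TypeError as exc:
            raise ValidationError(f"bad run config: {exc}") from exc
        return config.validate()

    def validate(self) -> "RunConfig":
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.reference not in ("patients_external", "patients_only"):
            raise ValidationError(f"unknown reference mode: {self.reference!r}")
        for name in ("patient_counts", "inhouse_cell_counts", "metadata"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValidationError(f"{name} path does not exist: {p}")
        if self.external_cell_counts and not Path(self.external_cell_counts).exists():
            raise ValidationError(
                f"external_cell_counts path does not exist: {self.external_cell_counts}"
            )
        return self


def run_resemblance_pipeline(config: RunConfig) -> dict:
    """Execute the full two-table procedure and write ranking/profile/log files.

    Stage order: merge to reference and combined tables; CPM; expression
    filter on the combined table; VST on the reference; IQR top-k on the
    reference; VST on the combined table; Spearman profiles over the frozen
    selection; exclusion-list removal; replicate averaging; summary/rank for
    all patients and per HRD subgroup.  Any stage error aborts the run and
    removes partial outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = [outdir / "profile.tsv", outdir / "ranking.tsv", outdir / "run_log.json"]
    log: dict = {"parameters": asdict(config), "stages": {}}
    stage = "load"
    try:
        annotation = counts_io.read_annotation(config.metadata)
        patients = counts_io.read_count_matrix(config.patient_counts)
        inhouse = counts_io.read_count_matrix(config.inhouse_cell_counts)
        external = (
            counts_io.read_count_matrix(config.external_cell_counts)
            if config.external_cell_counts
            else None
        )

        stage = "merge"
        ref_tables = [patients] + ([external] if external is not None else [])
        combined_tables = ref_tables + [inhouse]
        combined = counts_io.merge_on_shared_genes(combined_tables)
        log["stages"]["merge"] = {
            "genes_shared": combined.shape[0],
            "samples_combined": combined.shape[1],
        }

        stage = "sample_filters"
        combined = counts_io.apply_sample_filters(
            combined, annotation, keep_suffix=config.patient_suffix
        )
        log["stages"]["sample_filters"] = {"samples_retained": combined.shape[1]}

        stage = "cpm_filter"
        combined_cpm = counts_io.cpm(combined)
        keep = feature_selection.expression_filter(
            combined_cpm,
            threshold=config.cpm_threshold,
            min_samples=config.cpm_min_samples,
            source_table_id="combined",
        )
        combined = feature_selection.apply_selection(combined, keep)
        log["stages"]["cpm_filter"] = {"genes_after_filter": len(keep)}
        logger.info("expression filter retained %d genes", len(keep))

        ann = annotation.set_index("sample_id")
        patient_ids = [s for s in combined.columns if ann.loc[s, "cohort"] == "patient"]
        inhouse_ids = [s for s in combined.columns if s in inhouse.columns]
        external_ids = [
            s for s in combined.columns if s not in patient_ids and s not in inhouse_ids
        ]
        if config.reference == "patients_only":
            reference_ids = patient_ids
        else:
            reference_ids = patient_ids + external_ids
        reference = combined[reference_ids]

        stage = "vst_reference"
        ref_vst, ref_trend, _ = vst.blind_vst(reference)
        log["stages"]["vst_reference"] = {
            "a0": ref_trend.asymptotic_dispersion,
            "a1": ref_trend.extra_poisson,
            "iterations": ref_trend.n_iterations,
            "genes_used": ref_trend.n_genes_used,
        }

        stage = "top_variable_genes"
        selection = feature_selection.top_variable_genes(
            ref_vst, k=config.top_k, source_table_id="reference"
        )
        log["stages"]["top_variable_genes"] = {"genes_selected": len(selection)}

        stage = "vst_combined"
        comb_vst, comb_trend, _ = vst.blind_vst(combined)
        log["stages"]["vst_combined"] = {
            "a0": comb_trend.asymptotic_dispersion,
            "a1": comb_trend.extra_poisson,
            "iterations": comb_trend.n_iterations,
            "genes_used": comb_trend.n_genes_used,
        }

        stage = "spearman"
        cell_ids = external_ids + inhouse_ids
        profile = resemblance.spearman_profile(
            comb_vst[cell_ids], comb_vst[patient_ids], selection
        )

        stage = "exclusions"
        drop = [c for c in config.exclude_cell_lines if c in profile.index]
        profile = profile.drop(index=drop)
        log["stages"]["exclusions"] = {"cell_lines_removed": drop}

        stage = "average_replicates"
        replicate_map = {
            c: str(ann.loc[c, "replicate_group"]) for c in profile.index
        }
        profile = resemblance.average_replicates(profile, replicate_map)
        log["stages"]["average_replicates"] = {"cell_lines": profile.shape[0]}

        stage = "rank"
        subgroups = {
            p: ann.loc[p, "subgroup"] if ann.loc[p, "subgroup"] in ("HRD1", "HRD0") else "NA"
            for p in profile.columns
        }
        has_contrast = set(subgroups.values()) >= {"HRD1", "HRD0"} and "NA" not in set(
            subgroups.values()
        )
        if has_contrast:
            ranking = resemblance.subgroup_contrast(
                profile, annotation, summary=config.summary
            )
        else:
            ranking = resemblance.summarize_and_rank(profile, summary=config.summary)
        log["stages"]["rank"] = {
            "summary_statistic": config.summary,
            "subgroup_contrast": bool(has_contrast),
        }

        stage = "write"
        profile.round(6).to_csv(outdir / "profile.tsv", sep="\t", index_label="cell_line")
        ranking.to_csv(outdir / "ranking.tsv", sep="\t", index=False, float_format="%.6f")
        with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
    except LinesimError as exc:
        for f in outputs:
            f.unlink(missing_ok=True)
        raise StageError(stage, str(exc)) from exc
    return log


def run_marker_analysis(
    markers_path: str | Path, zero_policy: str = "exclude", outdir: str | Path = "."
) -> pd.DataFrame:
    """Compute per-marker R² and panel median, writing concordance.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_marker_table(markers_path)
    table = concordance_summary(records, zero_policy=zero_policy)
    out = table.copy()
    out["panel_median_r2"] = table.attrs["median_r2"]
    out.to_csv(outdir / "concordance.tsv", sep="\t", index=False, float_format="%.6f")
    return table
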