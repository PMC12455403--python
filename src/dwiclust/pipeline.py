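"""End-to-end orchestration: normative maps -> z -> enhancement -> clusters ->
resection overlap -> outcome statistics.

`run_subject` processes one patient against a prebuilt normative map;
`run_cohort` runs every patient (normative maps built strictly within scanner
cohort), classifies resection overlap, and produces the cohort tables: per-
subject overlap, category counts, year-1 seizure-freedom rates with 90%
Wilson intervals, Kaplan-Meier curves with log-rank tests, and rank-based
cluster count/volume comparisons between outcome groups.  Everything is
deterministic given inputs and config; warnings (e.g. a patient with zero
clusters) never abort a cohort run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import ClusterSet, apply_substantial_cut, summarize_clusters, threshold_and_label
from .normative import NormativeMap, ZMap, build_normative_map, zscore_subject
from .outcomes import (
    SubjectOutcome,
    TestResult,
    chisq_yates,
    compare_counts,
    km_logrank,
    proportion_ci90,
    seizure_free_at,
    to_survival,
)
from .ptfce import EnhancedZMap, PtfceConfig, ptfce_enhance
from .resection import OverlapResult, classify_subject
from .volume_io import BinaryMask, MetricVolume, assert_common_grid

log = logging.getLogger("dwiclust")


@dataclass
class PipelineConfig:
    """Analysis settings; round-trips losslessly through YAML."""

    metric: str = "MD"
    direction: str | None = None  # None = metric default
    z_threshold: float = 3.0
    connectivity: int = 26
    n_thresholds: int = 400
    smoothness_fwhm_mm: float | str = "estimate"
    sd_floor: float = 1e-6
    seed: int = 0

    def ptfce(self) -> PtfceConfig:
        return PtfceConfig(
            n_thresholds=self.n_thresholds,
            connectivity=self.connectivity,
            smoothness_fwhm_mm=self.smoothness_fwhm_mm,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class SubjectRecord:
    """All per-subject artifacts of one pipeline pass."""

    subject_id: str
    zmap: ZMap
    enhanced: EnhancedZMap
    cluster_set: ClusterSet
    overlap: OverlapResult | None


def run_subject(
    patient: MetricVolume,
    normative: NormativeMap,
    resection: BinaryMask | None,
    analysis_mask: BinaryMask,
    config: PipelineConfig | None = None,
) -> SubjectRecord:
    """Process one patient: z-score, enhance, cluster, classify overlap."""
    config = config or PipelineConfig()
    zmap = zscore_subject(patient, normative, direction=config.direction)
    enhanced = ptfce_enhance(zmap, analysis_mask, config.ptfce())
    cluster_set = threshold_and_label(
        enhanced, z_threshold=config.z_threshold, connectivity=config.connectivity
    )
    apply_substantial_cut(cluster_set)
    overlap = None
    if resection is not None:
        overlap = classify_subject(cluster_set, resection)
    return SubjectRecord(
        subject_id=patient.subject_id,
        zmap=zmap,
        enhanced=enhanced,
        cluster_set=cluster_set,
        overlap=overlap,
    )


@dataclass
class CohortResult:
    """Cohort tables and statistics; `write` emits CSV/JSON artifacts."""

    overlap_table: pd.DataFrame
    cluster_table: pd.DataFrame
    category_counts: dict[str, int]
    year1_rates: pd.DataFrame
    km_curves: pd.DataFrame | None
    logrank: TestResult | None
    cluster_count_test: TestResult | None
    cluster_volume_test: TestResult | None
    config_digest: str
    records: list[SubjectRecord] = field(default_factory=list, repr=False)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = {"config_digest": self.config_digest, "version": __version__}
        for df_name in ("overlap_table", "cluster_table", "year1_rates", "km_curves"):
            df = getattr(self, df_name)
            if df is None:
                continue
            df = df.copy()
            df.attrs.update(stamp)
            df.to_csv(outdir / f"{df_name}.csv", index=False)
        stats = {**stamp, "category_counts": self.category_counts}
        for name in ("logrank", "cluster_count_test", "cluster_volume_test"):
            t = getattr(self, name)
            if t is not None:
                stats[name] = asdict(t)
        (outdir / "statistics.json").write_text(json.dumps(stats, indent=2))


def run_cohort(
    controls: list[MetricVolume],
    patients: list[MetricVolume],
    analysis_mask: BinaryMask,
    resections: dict[str, BinaryMask],
    outcomes: list[SubjectOutcome],
    config: PipelineConfig | None = None,
    exclusion_mask: BinaryMask | None = None,
) -> CohortResult:
    """Run the full analysis over a cohort.

    Normative maps are built and applied strictly within scanner cohort
    (patients are matched to the map of their own ``cohort_id``).  Validation
    problems are collected exhaustively before aborting.
    """
    config = config or PipelineConfig()
    problems = []
    if len(patients) < 2:
        problems.append("need >= 2 patients")
    cohort_ids = sorted({c.cohort_id for c in controls})
    for cid in cohort_ids:
        if sum(c.cohort_id == cid for c in controls) < 3:
            problems.append(f"cohort {cid!r} has < 3 controls")
    missing = {p.cohort_id for p in patients} - set(cohort_ids)
    if missing:
        problems.append(f"patients reference cohorts without controls: {sorted(missing)}")
    if problems:
        raise ValueError("cohort validation failed: " + "; ".join(problems))
    assert_common_grid([*controls, *patients, analysis_mask, *resections.values()])

    normatives = {
        cid: build_normative_map(
            [c for c in controls if c.cohort_id == cid],
            analysis_mask,
            exclusion_mask,
            sd_floor=config.sd_floor,
        )
        for cid in cohort_ids
    }

    outcome_by_id = {o.subject_id: o for o in outcomes}
    records: list[SubjectRecord] = []
    for patient in patients:
        rec = run_subject(
            patient,
            normatives[patient.cohort_id],
            resections.get(patient.subject_id),
            analysis_mask,
            config,
        )
        if rec.cluster_set.n_clusters == 0:
            log.warning("subject %s: no clusters above threshold", patient.subject_id)
        records.append(rec)

    overlap_rows, cluster_rows = [], []
    for rec in records:
        summary = summarize_clusters(rec.cluster_set)
        for c in rec.cluster_set.clusters:
            cluster_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "rank": c.id,
                    "n_voxels": c.n_voxels,
                    "volume_mm3": c.volume_mm3,
                    "is_substantial": c.is_substantial,
                    "centroid_x_mm": c.centroid_mm[0],
                    "centroid_y_mm": c.centroid_mm[1],
                    "centroid_z_mm": c.centroid_mm[2],
                }
            )
        row = {
            "subject_id": rec.subject_id,
            "n_clusters": summary["n_clusters"],
            "n_substantial": summary["n_substantial"],
            "total_substantial_voxels": summary["total_substantial_voxels"],
        }
        if rec.overlap is not None:
            row.update(
                category=rec.overlap.category,
                proportion_bin=rec.overlap.proportion_bin,
                largest_resected=rec.overlap.largest_resected,
                fraction_largest=(
                    rec.overlap.resected_fractions[0]
                    if rec.overlap.resected_fractions
                    else np.nan
                ),
                resection_volume_mm3=rec.overlap.resection_volume_mm3,
            )
        o = outcome_by_id.get(rec.subject_id)
        if o is not None:
            row["seizure_free_y1"] = seizure_free_at(o, 1)
        overlap_rows.append(row)
    overlap_table = pd.DataFrame(overlap_rows)
    cluster_table = pd.DataFrame(cluster_rows)

    category_counts = (
        overlap_table["category"].value_counts().to_dict()
        if "category" in overlap_table
        else {}
    )

    # group-level statistics: resected vs spared largest cluster
    year1_rows = []
    km_curves, logrank = None, None
    count_test = volume_test = None
    if "largest_resected" in overlap_table and "seizure_free_y1" in overlap_table:
        merged = overlap_table.dropna(subset=["seizure_free_y1"])
        groups = {
            "largest_resected": merged[merged["largest_resected"] == True],
            "largest_spared": merged[merged["largest_resected"] == False],
        }
        for name, sub in groups.items():
            if len(sub):
                est, lo, hi = proportion_ci90(int(sub["seizure_free_y1"].sum()), len(sub))
                year1_rows.append(
                    {"group": name, "n": len(sub), "rate": est, "ci90_lo": lo, "ci90_hi": hi}
                )
        if all(len(sub) for sub in groups.values()):
            surv_groups = {
                name: [to_survival(outcome_by_id[s]) for s in sub["subject_id"]]
                for name, sub in groups.items()
            }
            km_curves, logrank = km_logrank(surv_groups)
            sf = merged[merged["seizure_free_y1"] == True]
            nsf = merged[merged["seizure_free_y1"] == False]
            if len(sf) and len(nsf):
                count_test = compare_counts(sf["n_substantial"], nsf["n_substantial"])
                volume_test = compare_counts(
                    sf["total_substantial_voxels"], nsf["total_substantial_voxels"]
                )
        else:
            log.warning("only one resection group present; no group contrast computed")
    return CohortResult(
        overlap_table=overlap_table,
        cluster_table=cluster_table,
        category_counts=category_counts,
        year1_rates=pd.DataFrame(year1_rows),
        km_curves=km_curves,
        logrank=logrank,
        cluster_count_test=count_test,
        cluster_volume_test=volume_test,
        config_digest=config.digest(),
        records=records,
    )
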