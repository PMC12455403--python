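"""Seeded synthetic cohort with the statistical structure the pipeline assumes.

No patient imaging is publicly available for this analysis, so every stage is
exercised against a generator that emulates the relevant structure:

- **Controls**: a spatially smooth Gaussian field (periodic convolution of
  white noise with a Gaussian kernel, FWHM 6 mm) around an MD-like background
  (0.8e-3 mm^2/s), marginal SD ``noise_sd``, clipped at zero.
- **Patients**: the same field plus planted ellipsoidal clusters whose voxel
  values are raised by ``planted_effect_delta`` control-SDs (default 4), with
  one dominant cluster (default radii 6/4/3 mm) plus a few spurious 1-2 voxel
  exceedances — a heavy-tailed cluster-size profile.
- **Resections**: a sphere placed by line search so its overlap with the
  planted largest cluster hits a per-patient target fraction within +-0.05.
- **Outcomes**: yearly ILAE classes whose year-1 seizure-freedom probability
  depends on whether the largest planted cluster was resected (defaults 0.83
  resected vs 0.55 spared), with group-specific later relapse hazards and
  yearly attrition.

Everything is driven by one integer seed through `numpy.random.SeedSequence`,
so the whole cohort — volumes, masks, outcomes — is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .outcomes import SubjectOutcome
from .volume_io import BinaryMask, MetricVolume, VolumeGrid, write_volume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the package's study conditions."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.0
    n_controls: int = 30
    n_patients: int = 60
    background_mean: float = 0.8e-3  # MD-like, mm^2/s
    noise_sd: float = 4e-5  # marginal SD of the control field, metric units
    smoothness_fwhm_mm: float = 6.0
    planted_effect_delta: float = 4.0  # planted raise, in control-SD units
    planted_radii_mm: tuple[float, ...] = (6.0, 4.0, 3.0)
    spurious_cluster_rate: float = 2.0  # mean number of 1-2 voxel exceedances
    resection_radius_mm: float = 10.0
    p_resected: float = 0.525  # fraction of patients whose target overlap > 0
    p_seizure_free_resected: float = 0.83
    p_seizure_free_spared: float = 0.55
    relapse_hazard_resected: float = 0.05
    relapse_hazard_spared: float = 0.12
    attrition_per_year: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.p_resected,
            self.p_seizure_free_resected,
            self.p_seizure_free_spared,
            self.relapse_hazard_resected,
            self.relapse_hazard_spared,
            self.attrition_per_year,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.planted_effect_delta < 0:
            raise ValueError("planted_effect_delta must be >= 0")
        if any(r <= 0 for r in self.planted_radii_mm):
            raise ValueError("planted radii must be positive")
        if self.noise_sd < 0 or self.background_mean < 0:
            raise ValueError("noise_sd and background_mean must be >= 0")


@dataclass
class GroundTruthEntry:
    """Planted truth for one patient: the recovery target of the tests."""

    subject_id: str
    cluster_indices: list[np.ndarray]  # (n,3) per planted cluster, size desc
    cluster_sizes: list[int]
    radii_mm: list[float]
    overlap_target: float = 0.0
    achieved_overlap: float = 0.0
    largest_resected: bool = False


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    grid: VolumeGrid
    analysis_mask: BinaryMask
    controls: list[MetricVolume]
    patients: list[MetricVolume]
    resections: dict[str, BinaryMask]
    outcomes: list[SubjectOutcome]
    ground_truth: dict[str, GroundTruthEntry]


def make_grid(config: SyntheticConfig) -> VolumeGrid:
    v = config.voxel_size_mm
    shape = config.grid_shape
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = -np.array(shape) * v / 2.0  # centred on the origin
    return VolumeGrid(shape=shape, affine=affine, space_label="synthetic")


def make_analysis_mask(config: SyntheticConfig) -> BinaryMask:
    """Ellipsoidal 'brain' occupying most of the grid."""
    grid = make_grid(config)
    shape = np.array(config.grid_shape)
    center = (shape - 1) / 2.0
    radii = shape * 0.45
    idx = np.indices(config.grid_shape).astype(float)
    d2 = sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    return BinaryMask(grid=grid, data=d2 <= 1.0, role="analysis_mask")


def _kernel_l2_norm(sigma_vox: float) -> float:
    """L2 norm of the separable discrete Gaussian kernel (per axis cubed)."""
    half = max(int(4 * sigma_vox + 0.5), 1)
    impulse = np.zeros(2 * half + 1)
    impulse[half] = 1.0
    w = ndimage.gaussian_filter1d(impulse, sigma_vox)
    return float(np.sqrt((w**2).sum()) ** 3)


def smooth_unit_field(rng: np.random.Generator, shape, sigma_vox: float) -> np.ndarray:
    """Stationary smooth Gaussian field with marginal SD exactly 1.

    Periodic (wrap) convolution keeps the field stationary up to the grid
    boundary, so the per-voxel SD is uniform — important for the normative
    calibration tests.
    """
    white = rng.standard_normal(shape)
    if sigma_vox <= 0:
        return white
    smoothed = ndimage.gaussian_filter(white, sigma_vox, mode="wrap")
    return smoothed / _kernel_l2_norm(sigma_vox)


def _control_field(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    sigma_vox = config.smoothness_fwhm_mm * FWHM_TO_SIGMA / config.voxel_size_mm
    field_ = smooth_unit_field(rng, config.grid_shape, sigma_vox)
    return np.maximum(config.background_mean + config.noise_sd * field_, 0.0)


def generate_controls(
    config: SyntheticConfig, cohort_id: str = "cohortA"
) -> list[MetricVolume]:
    """Deterministic control volumes: smooth noise around the background."""
    grid = make_grid(config)
    streams = np.random.SeedSequence([config.seed, 1]).spawn(config.n_controls)
    out = []
    for k, ss in enumerate(streams):
        data = _control_field(config, np.random.default_rng(ss))
        out.append(
            MetricVolume(
                grid=grid,
                metric="MD",
                data=data,
                subject_id=f"control{k:03d}",
                cohort_id=cohort_id,
            )
        )
    return out


def _ellipsoid_indices(center, radii_vox, shape) -> np.ndarray:
    lo = np.maximum(np.floor(center - radii_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + radii_vox + 1).astype(int) + 1, shape)
    sub = np.indices(tuple(hi - lo)).astype(float)
    d2 = sum(((sub[a] + lo[a] - center[a]) / radii_vox[a]) ** 2 for a in range(3))
    local = np.argwhere(d2 <= 1.0)
    return local + lo


def generate_patient(
    config: SyntheticConfig,
    rng: np.random.Generator,
    subject_id: str,
    cohort_id: str = "cohortA",
    analysis_mask: BinaryMask | None = None,
) -> tuple[MetricVolume, GroundTruthEntry]:
    """Control-like volume plus planted clusters; returns the ground truth.

    Planted clusters are mildly anisotropic ellipsoids (axis scale 0.85-1.15)
    with radii from ``planted_radii_mm``, pairwise disjoint with a margin,
    placed wholly inside the analysis mask; each raises the metric by
    ``planted_effect_delta * noise_sd``.  Spurious 1-2 voxel exceedances are
    added at the same amplitude (count ~ Poisson(spurious_cluster_rate)).
    """
    mask = analysis_mask or make_analysis_mask(config)
    grid = mask.grid
    shape = np.array(config.grid_shape)
    data = _control_field(config, rng)

    edt = ndimage.distance_transform_edt(mask.data)
    amplitude = config.planted_effect_delta * config.noise_sd
    centers: list[np.ndarray] = []
    radii_used: list[float] = []
    clusters: list[np.ndarray] = []
    radii_sorted = sorted(config.planted_radii_mm, reverse=True)
    for r_mm in radii_sorted:
        r_vox = r_mm / config.voxel_size_mm
        candidates = np.argwhere(edt >= r_vox + 1.5)
        if candidates.size == 0:
            raise ValueError(f"planted cluster radius {r_mm} mm does not fit the grid")
        placed = False
        for _ in range(200):
            c = candidates[rng.integers(len(candidates))].astype(float)
            ok = all(
                np.linalg.norm(c - prev) * config.voxel_size_mm
                >= r_mm + prev_r + 2 * config.voxel_size_mm
                for prev, prev_r in zip(centers, radii_used)
            )
            if ok:
                placed = True
                break
        if not placed:
            raise ValueError("could not place disjoint planted clusters on this grid")
        aniso = rng.uniform(0.85, 1.15, size=3)
        idx = _ellipsoid_indices(c, r_vox * aniso, shape)
        inside = mask.data[tuple(idx.T)]
        idx = idx[inside]
        data[tuple(idx.T)] += amplitude
        centers.append(c)
        radii_used.append(r_mm)
        clusters.append(idx)

    n_spurious = rng.poisson(config.spurious_cluster_rate)
    taken = np.zeros(tuple(shape), dtype=bool)
    for idx in clusters:
        taken[tuple(idx.T)] = True
    taken = ndimage.binary_dilation(taken, iterations=2)
    interior = np.argwhere(mask.data & ~taken & (edt >= 2))
    for _ in range(n_spurious):
        c = interior[rng.integers(len(interior))]
        size = int(rng.integers(1, 3))
        pts = [c]
        if size == 2:
            step = np.zeros(3, dtype=int)
            step[rng.integers(3)] = 1
            nb = np.clip(c + step, 0, shape - 1)
            if mask.data[tuple(nb)]:
                pts.append(nb)
        for p in pts:
            data[tuple(p)] += amplitude

    order = np.argsort([-len(i) for i in clusters], kind="stable")
    entry = GroundTruthEntry(
        subject_id=subject_id,
        cluster_indices=[clusters[k] for k in order],
        cluster_sizes=[int(len(clusters[k])) for k in order],
        radii_mm=[radii_used[k] for k in order],
    )
    vol = MetricVolume(
        grid=grid,
        metric="MD",
        data=np.maximum(data, 0.0),
        subject_id=subject_id,
        cohort_id=cohort_id,
    )
    return vol, entry


def generate_resection(
    config: SyntheticConfig,
    entry: GroundTruthEntry,
    rng: np.random.Generator,
    overlap_target: float,
    tolerance: float = 0.05,
    aim_cluster: int = 0,
) -> BinaryMask:
    """Spherical resection mask hitting the target overlap with the largest
    planted cluster (fraction within +-tolerance).

    The sphere centre moves along a random ray from the cluster centroid; the
    offset is found by fine scan.  ``overlap_target == 0`` guarantees exact
    disjointness from the largest cluster; *aim_cluster* selects which planted
    cluster the sphere is centred on in that case (0 = none: far from all).
    """
    if not 0.0 <= overlap_target <= 1.0:
        raise ValueError("overlap target must be in [0, 1]")
    grid = make_grid(config)
    shape = np.array(config.grid_shape)
    largest = entry.cluster_indices[0]
    centroid = largest.mean(axis=0)
    r_vox = config.resection_radius_mm / config.voxel_size_mm
    coords = np.indices(config.grid_shape).astype(float)

    def sphere_at(center: np.ndarray) -> np.ndarray:
        d2 = sum((coords[a] - center[a]) ** 2 for a in range(3))
        return d2 <= r_vox**2

    largest_mask = np.zeros(tuple(shape), dtype=bool)
    largest_mask[tuple(largest.T)] = True

    if overlap_target == 0.0:
        if 0 < aim_cluster < len(entry.cluster_indices):
            center = entry.cluster_indices[aim_cluster].mean(axis=0)
        else:
            # far corner region of the mask, away from every planted cluster
            center = shape * 0.75
        for _ in range(50):
            mask = sphere_at(center)
            if not (mask & largest_mask).any():
                break
            center = centroid + (center - centroid) * 1.2
        else:
            raise ValueError("cannot place a resection disjoint from the largest cluster")
        frac = 0.0
    else:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        best, best_err = None, np.inf
        for t in np.arange(0.0, 3.0 * r_vox, 0.25):
            center = centroid + direction * t
            mask = sphere_at(center)
            frac_t = (mask & largest_mask).sum() / largest_mask.sum()
            err = abs(frac_t - overlap_target)
            if err < best_err:
                best, best_err, frac = mask, err, frac_t
            if frac_t == 0.0:
                break
        if best_err > tolerance:
            raise ValueError(
                f"target overlap {overlap_target} unattainable on this grid "
                f"(best error {best_err:.3f})"
            )
        mask = best
    entry.overlap_target = float(overlap_target)
    entry.achieved_overlap = float(frac)
    entry.largest_resected = bool(frac > 0)
    return BinaryMask(grid=grid, data=mask, role="resection")


def generate_outcomes(
    config: SyntheticConfig,
    resected_flags: list[bool],
    rng: np.random.Generator,
    subject_ids: list[str] | None = None,
) -> list[SubjectOutcome]:
    """Yearly ILAE sequences from group-dependent Bernoulli/hazard draws.

    Year-1 seizure freedom is Bernoulli with the group probability; while
    free, each later year relapses with the group hazard; once relapsed the
    class stays >= 3.  Follow-up ends early with probability
    ``attrition_per_year`` per year after the first.
    """
    out = []
    for k, resected in enumerate(resected_flags):
        sid = subject_ids[k] if subject_ids else f"patient{k:03d}"
        p1 = config.p_seizure_free_resected if resected else config.p_seizure_free_spared
        hazard = (
            config.relapse_hazard_resected if resected else config.relapse_hazard_spared
        )
        free = rng.random() < p1
        ilae: list[int | None] = [_draw_class(rng, free)]
        for _year in range(2, 6):
            if rng.random() < config.attrition_per_year:
                break
            if free and rng.random() < hazard:
                free = False
            ilae.append(_draw_class(rng, free))
        out.append(SubjectOutcome(subject_id=sid, ilae_by_year=ilae))
    return out


def _draw_class(rng: np.random.Generator, free: bool) -> int:
    if free:
        return 1 if rng.random() < 0.8 else 2
    return int(rng.integers(3, 6))


def generate_cohort(config: SyntheticConfig, cohort_id: str = "cohortA") -> SyntheticCohort:
    """Full seeded cohort: controls, patients, resections, outcomes, truth."""
    grid = make_grid(config)
    mask = make_analysis_mask(config)
    controls = generate_controls(config, cohort_id=cohort_id)

    pat_streams = np.random.SeedSequence([config.seed, 2]).spawn(config.n_patients)
    rng_assign = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    patients, truth, resections = [], {}, {}
    flags, sids = [], []
    for k, ss in enumerate(pat_streams):
        rng = np.random.default_rng(ss)
        sid = f"patient{k:03d}"
        vol, entry = generate_patient(config, rng, sid, cohort_id, analysis_mask=mask)
        resect = rng_assign.random() < config.p_resected
        if resect:
            target = float(rng_assign.uniform(0.08, 1.0))
            aim = 0
        else:
            target = 0.0
            aim = 1 if rng_assign.random() < 0.5 else 0  # half hit another cluster
        resections[sid] = generate_resection(config, entry, rng, target, aim_cluster=aim)
        patients.append(vol)
        truth[sid] = entry
        flags.append(entry.largest_resected)
        sids.append(sid)

    rng_out = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    outcomes = generate_outcomes(config, flags, rng_out, subject_ids=sids)
    return SyntheticCohort(
        config=config,
        grid=grid,
        analysis_mask=mask,
        controls=controls,
        patients=patients,
        resections=resections,
        outcomes=outcomes,
        ground_truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the cohort to disk in the pipeline's input layout.

    ``controls/*.nii.gz``, ``patients/*.nii.gz``, ``resections/*.nii.gz``,
    ``analysis_mask.nii.gz``, ``outcomes.csv`` and ``ground_truth.json``.
    """
    outdir = Path(outdir)
    for sub in ("controls", "patients", "resections"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    write_volume(cohort.analysis_mask, outdir / "analysis_mask.nii.gz")
    for c in cohort.controls:
        write_volume(c, outdir / "controls" / f"{c.subject_id}.nii.gz")
    for p in cohort.patients:
        write_volume(p, outdir / "patients" / f"{p.subject_id}.nii.gz")
    for sid, m in cohort.resections.items():
        write_volume(m, outdir / "resections" / f"{sid}.nii.gz")

    rows = []
    for o in cohort.outcomes:
        row = {"subject_id": o.subject_id}
        for y in range(1, 6):
            row[f"ilae_year{y}"] = (
                o.ilae_by_year[y - 1] if y <= len(o.ilae_by_year) else None
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "outcomes.csv", index=False)

    gt = {
        sid: {
            "cluster_sizes": e.cluster_sizes,
            "radii_mm": e.radii_mm,
            "overlap_target": e.overlap_target,
            "achieved_overlap": e.achieved_overlap,
            "largest_resected": e.largest_resected,
            "cluster_indices": [i.tolist() for i in e.cluster_indices],
        }
        for sid, e in cohort.ground_truth.items()
    }
    meta = {"config": asdict(cohort.config), "cohort_id": cohort.controls[0].cohort_id}
    (outdir / "ground_truth.json").write_text(json.dumps({"meta": meta, "patients": gt}))
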