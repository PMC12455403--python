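"""Voxelwise normative modelling of diffusion-tensor metrics.

A normative map holds the per-voxel mean and sample SD of one metric across a
cohort of healthy controls.  Patients (or held-out controls) are z-scored
voxel-by-voxel against the map of their own scanner cohort: z = (x - mean)/sd,
the number of control SDs away from the healthy mean.  Normative maps are
always cohort-specific — z-scoring against another cohort's map is refused —
because scanner differences would otherwise masquerade as abnormality.

Covariates (age, sex) are deliberately not regressed out, and both gray and
white matter are retained; a white-matter-only analysis is expressed simply by
passing a tighter analysis mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import BinaryMask, MetricVolume, VolumeGrid, assert_common_grid

SD_FLOOR = 1e-6  # metric units; voxels at/below this SD are invalid

DIRECTIONS = ("positive", "negative", "two_sided")

#: Expected abnormality direction per metric: diffusivities increase in
#: pathological tissue, anisotropy decreases.
DEFAULT_DIRECTION = {"MD": "positive", "AD": "positive", "RD": "positive", "FA": "negative"}


class NormativeError(Exception):
    """Invalid inputs to normative-map construction or z-scoring."""


class CohortMismatchError(NormativeError):
    """Subject and normative map come from different scanner cohorts."""


@dataclass
class NormativeMap:
    """Per-voxel control mean and SD of one metric, with a valid-voxel mask."""

    grid: VolumeGrid
    metric: str
    mean: np.ndarray
    sd: np.ndarray
    n_controls: int
    valid: np.ndarray
    cohort_id: str = ""
    sd_floor: float = SD_FLOOR

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class ZMap:
    """Voxelwise abnormality z-scores; NaN exactly where the map is invalid."""

    grid: VolumeGrid
    metric: str
    z: np.ndarray
    subject_id: str = ""
    direction: str = "positive"

    def one_sided(self) -> np.ndarray:
        """Non-negative abnormality scores per the configured direction.

        ``positive`` clamps negative z at 0, ``negative`` negates first (so FA
        decreases score positively), ``two_sided`` takes |z|.  NaNs pass
        through unchanged.
        """
        z = self.z
        if self.direction == "positive":
            out = np.where(np.isnan(z), np.nan, np.maximum(z, 0.0))
        elif self.direction == "negative":
            out = np.where(np.isnan(z), np.nan, np.maximum(-z, 0.0))
        elif self.direction == "two_sided":
            out = np.abs(z)
        else:  # pragma: no cover - guarded at construction
            raise ValueError(f"unknown direction {self.direction!r}")
        return out.astype(np.float32)

    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.z)


def build_normative_map(
    controls: list[MetricVolume],
    analysis_mask: BinaryMask,
    exclusion_mask: BinaryMask | None = None,
    sd_floor: float = SD_FLOOR,
) -> NormativeMap:
    """Build the per-voxel normative distribution from >= 3 controls.

    Mean and sample SD (denominator n-1) are computed per voxel across
    controls.  A voxel is valid when it lies inside the analysis mask, outside
    the exclusion mask, and its control SD exceeds *sd_floor* (degenerate
    voxels would yield unbounded z-scores).
    """
    if len(controls) < 3:
        raise NormativeError(f"need >= 3 controls, got {len(controls)}")
    metrics = {c.metric for c in controls}
    if len(metrics) != 1:
        raise NormativeError(f"controls mix metrics: {sorted(metrics)}")
    cohorts = {c.cohort_id for c in controls}
    if len(cohorts) != 1:
        raise NormativeError(
            f"controls mix cohorts {sorted(cohorts)}; build one map per cohort"
        )
    to_check = [*controls, analysis_mask] + ([exclusion_mask] if exclusion_mask else [])
    grid = assert_common_grid(to_check)

    stack = np.stack([c.data for c in controls]).astype(np.float64)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)

    valid = analysis_mask.data & (sd > sd_floor)
    if exclusion_mask is not None:
        valid &= ~exclusion_mask.data

    return NormativeMap(
        grid=grid,
        metric=metrics.pop(),
        mean=mean.astype(np.float32),
        sd=sd.astype(np.float32),
        n_controls=len(controls),
        valid=valid,
        cohort_id=cohorts.pop(),
        sd_floor=sd_floor,
    )


def zscore_subject(
    subject: MetricVolume,
    normative: NormativeMap,
    direction: str | None = None,
    allow_cohort_mismatch: bool = False,
) -> ZMap:
    """z-score a subject volume against the normative map of its own cohort.

    The returned z is signed; sidedness is recorded and applied later via
    :meth:`ZMap.one_sided`.  *direction* defaults to the metric's expected
    abnormality direction (increase for MD/AD/RD, decrease for FA).
    """
    if subject.metric != normative.metric:
        raise NormativeError(
            f"metric mismatch: subject {subject.metric}, map {normative.metric}"
        )
    if subject.cohort_id != normative.cohort_id and not allow_cohort_mismatch:
        raise CohortMismatchError(
            f"subject cohort {subject.cohort_id!r} != map cohort "
            f"{normative.cohort_id!r}; z-scoring across scanners is refused"
        )
    assert_common_grid([subject, normative])
    if direction is None:
        direction = DEFAULT_DIRECTION[subject.metric]
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (subject.data.astype(np.float64) - normative.mean) / normative.sd
    z = np.where(normative.valid, z, np.nan).astype(np.float32)
    return ZMap(
        grid=normative.grid,
        metric=subject.metric,
        z=z,
        subject_id=subject.subject_id,
        direction=direction,
    )
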