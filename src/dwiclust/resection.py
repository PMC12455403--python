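"""Overlap between abnormality clusters and the surgical resection mask.

A cluster counts as *resected* if it shares at least one voxel with the
resection mask — no minimum fraction.  For each subject the resected fraction
of every substantial cluster is computed exactly as a voxel-count ratio, and
the subject is assigned to one of four mutually exclusive categories used by
the outcome analysis:

- ``LARGEST_RESECTED``      — the largest cluster overlaps the resection;
- ``SPARED_OTHER_RESECTED`` — largest spared, some other substantial cluster resected;
- ``SPARED_NONE_RESECTED``  — largest spared, other substantial clusters exist, none resected;
- ``SPARED_NO_OTHER``       — largest spared and it is the only substantial cluster.

The largest-cluster resected fraction is additionally binned: NONE (0),
SMALL (0 < f <= 0.30), MID (0.30 < f < 0.70), LARGE (f >= 0.70); the
boundaries are inclusive on the outer bins ("no more than 30%", "at least
70%").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clusters import Cluster, ClusterSet
from .volume_io import BinaryMask, GridMismatchError

CATEGORIES = (
    "LARGEST_RESECTED",
    "SPARED_OTHER_RESECTED",
    "SPARED_NONE_RESECTED",
    "SPARED_NO_OTHER",
)

PROPORTION_BINS = ("NONE", "SMALL", "MID", "LARGE")


@dataclass
class OverlapResult:
    """Per-subject resection-overlap summary."""

    subject_id: str
    resected_fractions: list[float]  # per substantial cluster, rank order
    largest_resected: bool
    any_substantial_resected: bool
    category: str
    proportion_bin: str
    resection_volume_mm3: float


def overlap_proportion(cluster: Cluster, resection: BinaryMask) -> float:
    """Exact fraction of the cluster's voxels inside the resection mask."""
    idx = cluster.voxel_indices
    if np.any(idx >= np.array(resection.grid.shape)) or np.any(idx < 0):
        raise GridMismatchError("cluster voxel indices fall outside the mask grid")
    inside = resection.data[tuple(idx.T)]
    return float(inside.sum()) / cluster.n_voxels


def proportion_bin(fraction: float) -> str:
    """Bin the largest-cluster resected fraction per the outcome analysis."""
    if fraction == 0:
        return "NONE"
    if fraction <= 0.30:
        return "SMALL"
    if fraction >= 0.70:
        return "LARGE"
    return "MID"


def classify_subject(cluster_set: ClusterSet, resection: BinaryMask) -> OverlapResult:
    """Assign a subject to an overlap category from its substantial clusters.

    Requires the substantial cut to have been computed.  The category depends
    only on which substantial clusters have nonzero overlap, never on cluster
    internals.  Subjects with zero clusters are classified SPARED_NO_OTHER
    with an empty fraction list (degenerate but valid).
    """
    if cluster_set.n_clusters > 0 and cluster_set.n_substantial == 0:
        raise ValueError("run apply_substantial_cut before classify_subject")
    if cluster_set.n_clusters > 0 and cluster_set.grid.shape != resection.grid.shape:
        raise GridMismatchError("cluster set and resection mask grids differ")
    fractions = [overlap_proportion(c, resection) for c in cluster_set.substantial()]
    largest = bool(fractions and fractions[0] > 0)
    any_sub = any(f > 0 for f in fractions)
    if largest:
        category = "LARGEST_RESECTED"
    elif len(fractions) <= 1:
        category = "SPARED_NO_OTHER"
    elif any(f > 0 for f in fractions[1:]):
        category = "SPARED_OTHER_RESECTED"
    else:
        category = "SPARED_NONE_RESECTED"
    return OverlapResult(
        subject_id=cluster_set.subject_id,
        resected_fractions=fractions,
        largest_resected=largest,
        any_substantial_resected=any_sub,
        category=category,
        proportion_bin=proportion_bin(fractions[0]) if fractions else "NONE",
        resection_volume_mm3=resection_size(resection),
    )


def resection_size(resection: BinaryMask) -> float:
    """Resection volume in mm^3 (voxel count x voxel volume)."""
    return resection.volume_mm3()
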