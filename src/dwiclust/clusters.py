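"""Cluster extraction and the data-driven "substantial cluster" threshold.

Abnormal voxels are those whose (enhanced) z exceeds a threshold (default 3).
Connected components of abnormal voxels are ranked by extent, largest first.
Within a subject the ranked volume sequence typically shows a few large
clusters followed by a tail of small, potentially spurious ones; the cut
between the two regimes is found by single change-point analysis under a
gamma observation model: every break position is scored by the two-segment
gamma maximum likelihood, and the best break is accepted only if it beats the
one-segment fit by a fixed penalty.  Clusters before the break are
"substantial"; the largest cluster is substantial by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import gammaln, polygamma, psi

from .ptfce import CONNECTIVITY_STRUCTURES, EnhancedZMap
from .volume_io import GridMismatchError, VolumeGrid

#: Two-segment fits must beat the one-segment fit by this many log-likelihood
#: units, else only the largest cluster is substantial.
CHANGEPOINT_PENALTY = 2.0

#: Upper bound on the gamma shape so singleton segments (one cluster) have a
#: finite maximised likelihood.  Shape 100 means CV >= 10% — tighter volume
#: sequences are beyond realistic precision — and keeps the spurious
#: likelihood bonus of a degenerate segment below the acceptance penalty.
#: Shape is scale-free, so the cap preserves scale invariance of the break.
SHAPE_CAP = 100.0


@dataclass
class Cluster:
    """One connected component of abnormal voxels."""

    id: int  # rank, 1 = largest
    voxel_indices: np.ndarray  # (n, 3) int array of 0-based indices
    n_voxels: int
    volume_mm3: float
    centroid_mm: tuple[float, float, float]
    is_substantial: bool = False


@dataclass
class ClusterSet:
    """Volume-ranked clusters of one subject plus the substantial cut."""

    subject_id: str
    z_threshold: float
    connectivity: int
    grid: VolumeGrid
    clusters: list[Cluster] = field(default_factory=list)
    n_substantial: int = 0
    changepoint_loglik: float = float("nan")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def volumes_mm3(self) -> np.ndarray:
        return np.array([c.volume_mm3 for c in self.clusters])

    def substantial(self) -> list[Cluster]:
        return self.clusters[: self.n_substantial]

    def label_map(self) -> np.ndarray:
        """Integer volume: 0 = background, k = rank-k cluster."""
        out = np.zeros(self.grid.shape, dtype=np.int32)
        for c in self.clusters:
            out[tuple(c.voxel_indices.T)] = c.id
        return out


def threshold_and_label(
    enhanced: EnhancedZMap,
    z_threshold: float = 3.0,
    connectivity: int = 26,
) -> ClusterSet:
    """Label connected components of {z_enh > threshold}, ranked by extent.

    Ranking is by voxel count, descending; ties are broken by the
    lexicographically smallest voxel index so output is deterministic.  An
    empty result (no suprathreshold voxel) is valid.
    """
    if connectivity not in CONNECTIVITY_STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    grid = enhanced.grid
    sup = np.where(np.isnan(enhanced.z_enh), False, enhanced.z_enh > z_threshold)
    labels, n_lab = ndimage.label(sup, structure=CONNECTIVITY_STRUCTURES[connectivity])
    clusters: list[Cluster] = []
    if n_lab:
        sizes = np.bincount(labels.ravel())[1:]
        coords = np.argwhere(sup)
        flat_labels = labels[sup]
        order_in_label = np.argsort(flat_labels, kind="stable")
        coords = coords[order_in_label]  # grouped by label id 1..n_lab
        split_points = np.r_[0, np.cumsum(sizes)]
        groups = [coords[split_points[k] : split_points[k + 1]] for k in range(n_lab)]
        # rank by size desc, tie-break by smallest first voxel index
        first_voxel = [tuple(g[0]) for g in groups]
        order = sorted(range(n_lab), key=lambda k: (-sizes[k], first_voxel[k]))
        vv = grid.voxel_volume_mm3
        for rank, k in enumerate(order, start=1):
            g = groups[k]
            centroid = grid.voxel_to_world(g.mean(axis=0))[0]
            clusters.append(
                Cluster(
                    id=rank,
                    voxel_indices=g,
                    n_voxels=int(sizes[k]),
                    volume_mm3=float(sizes[k] * vv),
                    centroid_mm=tuple(float(x) for x in centroid),
                )
            )
    return ClusterSet(
        subject_id=enhanced.subject_id,
        z_threshold=z_threshold,
        connectivity=connectivity,
        grid=grid,
        clusters=clusters,
    )


def _gamma_mle(x: np.ndarray) -> tuple[float, float, float]:
    """Gamma MLE (shape, scale, loglik) with the shape capped at SHAPE_CAP.

    Shape solves log(k) - psi(k) = log(mean) - mean(log), by Newton iteration
    from the standard closed-form start; degenerate segments (one element or
    zero spread) sit at the cap.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    m = x.mean()
    s = np.log(m) - np.mean(np.log(x))
    if s <= 1e-12:  # zero spread: shape unbounded, cap it
        k = SHAPE_CAP
    else:
        k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
        for _ in range(50):
            f = np.log(k) - psi(k) - s
            fp = 1.0 / k - polygamma(1, k)
            step = f / fp
            k_new = k - step
            if k_new <= 0:
                k_new = k / 2.0
            if abs(k_new - k) < 1e-10 * k:
                k = k_new
                break
            k = k_new
        k = min(k, SHAPE_CAP)
    theta = m / k
    ll = float(
        np.sum((k - 1.0) * np.log(x) - x / theta) - n * (gammaln(k) + k * np.log(theta))
    )
    return float(k), float(theta), ll


def detect_substantial(
    cluster_volumes: np.ndarray | list[float],
    penalty: float = CHANGEPOINT_PENALTY,
) -> tuple[int, dict]:
    """Find how many leading clusters are "substantially large".

    Scans every break position b in the rank-ordered (non-increasing) volume
    sequence, fitting a gamma distribution to each side by maximum likelihood
    (shape and rate free per segment).  The break maximising the two-segment
    log-likelihood wins if it beats the one-segment fit by *penalty*
    log-likelihood units; otherwise, or with a single cluster, only the
    largest cluster is substantial.  The decision is invariant to rescaling
    all volumes by a positive constant.
    """
    v = np.asarray(cluster_volumes, dtype=float)
    if v.size == 0:
        raise ValueError("detect_substantial requires at least one cluster")
    if np.any(v <= 0):
        raise ValueError("cluster volumes must be positive")
    if np.any(np.diff(v) > 1e-9 * v[:-1]):
        raise ValueError("cluster volumes must be rank-ordered, non-increasing")
    diagnostics: dict = {"n_clusters": int(v.size), "penalty": penalty}
    if v.size == 1:
        diagnostics["reason"] = "single cluster"
        return 1, diagnostics

    _, _, ll_one = _gamma_mle(v)
    best_b, best_ll = None, -np.inf
    for b in range(1, v.size):  # segments [0:b], [b:]
        _, _, ll_left = _gamma_mle(v[:b])
        _, _, ll_right = _gamma_mle(v[b:])
        ll = ll_left + ll_right
        if ll > best_ll:
            best_b, best_ll = b, ll
    diagnostics.update(
        loglik_one_segment=ll_one,
        loglik_two_segment=float(best_ll),
        best_break=int(best_b),
    )
    if best_ll - ll_one < penalty:
        diagnostics["reason"] = "no break beats the one-segment fit"
        return 1, diagnostics
    diagnostics["reason"] = "change point accepted"
    return int(best_b), diagnostics


def apply_substantial_cut(cluster_set: ClusterSet, penalty: float = CHANGEPOINT_PENALTY) -> ClusterSet:
    """Run change-point detection on a ClusterSet and flag substantial clusters."""
    if cluster_set.n_clusters == 0:
        cluster_set.n_substantial = 0
        return cluster_set
    n_sub, diag = detect_substantial(cluster_set.volumes_mm3(), penalty=penalty)
    cluster_set.n_substantial = n_sub
    cluster_set.changepoint_loglik = diag.get("loglik_two_segment", float("nan"))
    for c in cluster_set.clusters:
        c.is_substantial = c.id <= n_sub
    return cluster_set


def summarize_clusters(cluster_set: ClusterSet, lobe_atlas: np.ndarray | None = None) -> dict:
    """Per-subject summary over substantial clusters only.

    A lobe is "touched" if at least one substantial-cluster voxel carries its
    (nonzero) atlas label.  The atlas, if given, must be on the common grid.
    """
    if lobe_atlas is not None and lobe_atlas.shape != cluster_set.grid.shape:
        raise GridMismatchError(
            f"atlas shape {lobe_atlas.shape} != grid {cluster_set.grid.shape}"
        )
    subs = cluster_set.substantial()
    total_voxels = int(sum(c.n_voxels for c in subs))
    summary = {
        "subject_id": cluster_set.subject_id,
        "n_clusters": cluster_set.n_clusters,
        "n_substantial": cluster_set.n_substantial,
        "total_substantial_voxels": total_voxels,
        "total_substantial_mm3": total_voxels * cluster_set.grid.voxel_volume_mm3,
    }
    if lobe_atlas is not None:
        touched: set[int] = set()
        for c in subs:
            labels = lobe_atlas[tuple(c.voxel_indices.T)]
            touched |= set(int(l) for l in np.unique(labels) if l != 0)
        summary["lobes_touched"] = sorted(touched)
        summary["n_lobes_touched"] = len(touched)
    return summary
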