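"""Cluster labeling against a brute-force oracle, and the substantial cut."""

import numpy as np
import pytest

from dwiclust.clusters import (
    apply_substantial_cut,
    detect_substantial,
    summarize_clusters,
    threshold_and_label,
)
from dwiclust.ptfce import EnhancedZMap, PtfceConfig
from dwiclust.volume_io import GridMismatchError, VolumeGrid

OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    18: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    26: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
}


def flood_fill_sizes(binary: np.ndarray, connectivity: int) -> list[int]:
    """Independent BFS component labeling; returns sizes, descending."""
    seen = np.zeros(binary.shape, bool)
    sizes = []
    shape = binary.shape
    for start in np.argwhere(binary):
        start = tuple(start)
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            p = stack.pop()
            size += 1
            for off in OFFSETS[connectivity]:
                q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
                if all(0 <= q[d] < shape[d] for d in range(3)) and binary[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        sizes.append(size)
    return sorted(sizes, reverse=True)


def _enh(arr: np.ndarray, voxel=2.0) -> EnhancedZMap:
    grid = VolumeGrid(arr.shape, np.diag([voxel, voxel, voxel, 1.0]))
    return EnhancedZMap(grid, arr.astype(np.float32), PtfceConfig(), "s")


def test_empty_map_yields_zero_clusters():
    cs = threshold_and_label(_enh(np.zeros((8, 8, 8))))
    assert cs.n_clusters == 0
    cs = apply_substantial_cut(cs)
    assert cs.n_substantial == 0


def test_two_planted_blobs_ranked_by_size():
    arr = np.zeros((16, 16, 16))
    arr[2:7, 2:4, 2] = 4.0  # 10 voxels
    arr[10:12, 10:12, 10] = 4.0  # 4 voxels
    cs = threshold_and_label(_enh(arr), z_threshold=3.0)
    assert [c.n_voxels for c in cs.clusters] == [10, 4]
    assert cs.clusters[0].volume_mm3 == pytest.approx(10 * 8.0)
    assert flood_fill_sizes(arr > 3, 26) == [10, 4]


def test_diagonal_touch_depends_on_connectivity():
    arr = np.zeros((8, 8, 8))
    arr[2, 2, 2] = 4.0
    arr[3, 3, 3] = 4.0
    assert threshold_and_label(_enh(arr), connectivity=26).n_clusters == 1
    assert threshold_and_label(_enh(arr), connectivity=6).n_clusters == 2


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_labeling_matches_flood_fill_on_random_volumes(connectivity):
    rng = np.random.default_rng(connectivity)
    for _ in range(30):
        p = rng.uniform(0.1, 0.6)
        arr = (rng.random((8, 8, 8)) < p) * 4.0
        cs = threshold_and_label(_enh(arr), z_threshold=3.0, connectivity=connectivity)
        assert [c.n_voxels for c in cs.clusters] == flood_fill_sizes(arr > 3, connectivity)


def test_equal_size_tie_break_is_deterministic():
    arr = np.zeros((16, 16, 16))
    arr[10:12, 10, 10] = 4.0  # 2 voxels, later in scan order
    arr[2:4, 2, 2] = 4.0  # 2 voxels, earlier
    cs = threshold_and_label(_enh(arr))
    assert tuple(cs.clusters[0].voxel_indices[0]) == (2, 2, 2)


class TestDetectSubstantial:
    def test_single_cluster_is_substantial(self):
        assert detect_substantial([500.0])[0] == 1

    def test_three_large_clusters_split_from_spurious_tail(self):
        n, diag = detect_substantial([1200, 950, 700, 25, 18, 9, 4])
        assert n == 3
        assert diag["reason"] == "change point accepted"

    def test_scale_invariance(self):
        v = np.array([1200, 950, 700, 25, 18, 9, 4], dtype=float)
        for scale in (1e-3, 1.0, 3.7, 1e4):
            assert detect_substantial(v * scale)[0] == 3

    def test_degenerate_equal_volumes_keep_only_largest(self):
        # every split fits exactly as well as no split, so the penalty
        # rejects the break and only the largest cluster is substantial
        n, diag = detect_substantial([50.0] * 8)
        assert n == 1
        assert diag["reason"] == "no break beats the one-segment fit"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            detect_substantial([])
        with pytest.raises(ValueError):
            detect_substantial([10.0, -1.0])
        with pytest.raises(ValueError):
            detect_substantial([1.0, 5.0])  # not rank-ordered


class TestSummarize:
    def _cluster_set(self):
        arr = np.zeros((16, 16, 16))
        arr[2:7, 2:6, 2:7] = 4.0  # 100 voxels
        arr[10:12, 10:12, 10:12] = 4.0  # 8 voxels
        cs = threshold_and_label(_enh(arr))
        cs.n_substantial = 2
        for c in cs.clusters:
            c.is_substantial = True
        return cs

    def test_totals_over_substantial_only(self):
        cs = self._cluster_set()
        s = summarize_clusters(cs)
        assert s["total_substantial_voxels"] == 108
        cs.n_substantial = 1
        assert summarize_clusters(cs)["total_substantial_voxels"] == 100

    def test_lobes_touched(self):
        cs = self._cluster_set()
        atlas = np.zeros((16, 16, 16), dtype=int)
        atlas[:5] = 1
        atlas[5:] = 2  # the 100-voxel cluster straddles both labels
        s = summarize_clusters(cs, lobe_atlas=atlas)
        assert s["lobes_touched"] == [1, 2]

    def test_atlas_grid_mismatch(self):
        with pytest.raises(GridMismatchError):
            summarize_clusters(self._cluster_set(), lobe_atlas=np.zeros((4, 4, 4), int))
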