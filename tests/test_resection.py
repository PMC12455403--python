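"""Resection overlap arithmetic, proportion bins, and subject categories."""

import numpy as np
import pytest
from scipy import ndimage

from dwiclust.clusters import apply_substantial_cut, threshold_and_label
from dwiclust.ptfce import EnhancedZMap, PtfceConfig
from dwiclust.resection import (
    classify_subject,
    overlap_proportion,
    proportion_bin,
    resection_size,
)
from dwiclust.volume_io import BinaryMask, VolumeGrid


def _grid(shape=(16, 16, 16)):
    return VolumeGrid(shape, np.diag([2.0, 2.0, 2.0, 1.0]))


def _cluster_set(blobs, grid=None, n_substantial=None):
    """Build a ClusterSet from a list of slice-tuples (largest first)."""
    grid = grid or _grid()
    arr = np.zeros(grid.shape, np.float32)
    for sl in blobs:
        arr[sl] = 4.0
    cs = threshold_and_label(EnhancedZMap(grid, arr, PtfceConfig(), "s"))
    cs.n_substantial = len(cs.clusters) if n_substantial is None else n_substantial
    for c in cs.clusters:
        c.is_substantial = c.id <= cs.n_substantial
    return cs


def _mask(data, grid=None):
    return BinaryMask(grid or _grid(), data, role="resection")


def test_disjoint_full_and_partial_overlap():
    cs = _cluster_set([(slice(2, 7), slice(2, 4), 2)])  # 10-voxel cluster
    cl = cs.clusters[0]
    empty = _mask(np.zeros((16, 16, 16), bool))
    assert overlap_proportion(cl, empty) == 0.0
    full = _mask(np.ones((16, 16, 16), bool))
    assert overlap_proportion(cl, full) == 1.0
    partial = np.zeros((16, 16, 16), bool)
    partial[2:5, 2, 2] = True  # 3 of the 10 cluster voxels
    assert overlap_proportion(cl, _mask(partial)) == pytest.approx(0.3)


def test_overlap_monotone_under_mask_dilation():
    rng = np.random.default_rng(0)
    cs = _cluster_set([(slice(4, 10), slice(4, 10), slice(4, 10))])
    cl = cs.clusters[0]
    m = rng.random((16, 16, 16)) > 0.9
    prev = overlap_proportion(cl, _mask(m))
    for _ in range(4):
        m = ndimage.binary_dilation(m)
        cur = overlap_proportion(cl, _mask(m))
        assert cur >= prev
        prev = cur


def test_proportion_bins_match_reported_boundaries():
    assert proportion_bin(0.0) == "NONE"
    assert proportion_bin(0.13) == "SMALL"  # the reported small-overlap example
    assert proportion_bin(0.30) == "SMALL"  # "no more than 30%" is inclusive
    assert proportion_bin(0.5) == "MID"
    assert proportion_bin(0.70) == "LARGE"  # "at least 70%" is inclusive
    assert proportion_bin(0.86) == "LARGE"
    assert proportion_bin(1.0) == "LARGE"


class TestClassifySubject:
    def test_largest_resected_small_proportion(self):
        cs = _cluster_set([(slice(2, 10), slice(2, 6), slice(2, 6))])
        cl = cs.clusters[0]
        m = np.zeros((16, 16, 16), bool)
        n_hit = int(round(0.13 * cl.n_voxels))
        m[tuple(cl.voxel_indices[:n_hit].T)] = True
        res = classify_subject(cs, _mask(m))
        assert res.category == "LARGEST_RESECTED"
        assert res.proportion_bin == "SMALL"
        assert res.largest_resected

    def test_spared_no_other(self):
        cs = _cluster_set([(slice(2, 7), slice(2, 4), 2)], n_substantial=1)
        res = classify_subject(cs, _mask(np.zeros((16, 16, 16), bool)))
        assert res.category == "SPARED_NO_OTHER"
        assert not res.any_substantial_resected

    def test_spared_other_resected(self):
        cs = _cluster_set(
            [
                (slice(2, 7), slice(2, 6), slice(2, 6)),  # rank 1
                (slice(10, 13), slice(10, 13), slice(10, 12)),  # rank 2
                (slice(10, 12), slice(2, 4), 12),  # rank 3
            ]
        )
        m = np.zeros((16, 16, 16), bool)
        m[11, 11, 10] = True  # one voxel of rank 2: "any overlap" counts
        res = classify_subject(cs, _mask(m))
        assert res.category == "SPARED_OTHER_RESECTED"
        assert res.resected_fractions[0] == 0.0
        assert res.resected_fractions[1] > 0.0

    def test_spared_none_resected(self):
        cs = _cluster_set(
            [
                (slice(2, 7), slice(2, 6), slice(2, 6)),
                (slice(10, 13), slice(10, 13), slice(10, 12)),
            ]
        )
        res = classify_subject(cs, _mask(np.zeros((16, 16, 16), bool)))
        assert res.category == "SPARED_NONE_RESECTED"

    def test_category_ignores_cluster_internals(self):
        # permuting which exact voxels overlap, at fixed fractions, keeps
        # the category fixed
        cs = _cluster_set([(slice(2, 10), slice(2, 6), slice(2, 6))])
        cl = cs.clusters[0]
        rng = np.random.default_rng(1)
        cats = set()
        for _ in range(5):
            pick = rng.choice(cl.n_voxels, size=10, replace=False)
            m = np.zeros((16, 16, 16), bool)
            m[tuple(cl.voxel_indices[pick].T)] = True
            cats.add(classify_subject(cs, _mask(m)).category)
        assert cats == {"LARGEST_RESECTED"}


def test_resection_size_arithmetic_and_sphere():
    empty = _mask(np.zeros((16, 16, 16), bool))
    assert resection_size(empty) == 0.0
    hundred = np.zeros((16, 16, 16), bool)
    hundred.ravel()[:100] = True
    assert resection_size(_mask(hundred)) == pytest.approx(800.0)  # 2 mm voxels

    grid = VolumeGrid((24, 24, 24), np.diag([2.0, 2.0, 2.0, 1.0]))
    idx = np.indices((24, 24, 24))
    d2 = sum((idx[a] - 11.5) ** 2 for a in range(3))
    sphere = _mask(d2 <= 5.0**2, grid)  # radius 10 mm = 5 voxels
    expected = 4.0 / 3.0 * np.pi * 10.0**3
    assert resection_size(sphere) == pytest.approx(expected, rel=0.10)
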