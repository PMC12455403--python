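"""NIfTI volume and mask I/O on a single common voxel grid.

All volumes entering the pipeline must already live on one voxel grid (the
clinical use case registers everything to MNI-152 at 2 mm upstream).  This
module deliberately contains no resampling: a grid mismatch is a hard error,
never silently corrected, so that misregistered inputs cannot slip through.

Conventions: voxel indices are 0-based; masked-out voxels in metric or z maps
carry NaN (zero is a valid metric value); boolean masks are strict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

METRICS = ("MD", "FA", "AD", "RD")

AFFINE_ATOL = 1e-4


class VolumeIOError(Exception):
    """Base class for volume I/O failures."""


class FileMissingError(VolumeIOError):
    """The requested NIfTI file does not exist."""


class NotScalarVolumeError(VolumeIOError):
    """The NIfTI file is not a 3D scalar volume (e.g. a 4D series)."""


class GridMismatchError(VolumeIOError):
    """Two volumes do not share the same voxel grid."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid: array shape plus the voxel-to-world affine.

    Parameters
    ----------
    shape
        Voxels per axis, all >= 1.
    affine
        4x4 matrix mapping 0-based voxel indices to world mm coordinates.
    space_label
        Free-text name of the space the grid lives in (e.g. ``"MNI152"``).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    space_label: str = "unknown"

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if np.any(self.voxel_size_from(affine) <= 0):
            raise ValueError("voxel sizes derived from affine must be > 0")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @staticmethod
    def voxel_size_from(affine: np.ndarray) -> np.ndarray:
        return np.sqrt((np.asarray(affine, dtype=float)[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(self.voxel_size_from(self.affine))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "VolumeGrid", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        homog = np.c_[idx, np.ones(len(idx))]
        return (self.affine @ homog.T).T[:, :3]


@dataclass
class MetricVolume:
    """One subject's scalar diffusion-metric map (MD, FA, AD or RD)."""

    grid: VolumeGrid
    metric: str
    data: np.ndarray
    subject_id: str = ""
    cohort_id: str = ""

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )


MASK_ROLES = ("analysis_mask", "exclusion", "resection")


@dataclass
class BinaryMask:
    """A strictly boolean mask on the common grid."""

    grid: VolumeGrid
    data: np.ndarray
    role: str = "analysis_mask"

    def __post_init__(self) -> None:
        if self.role not in MASK_ROLES:
            raise ValueError(f"role must be one of {MASK_ROLES}, got {self.role!r}")
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3


def _grid_from_header(img: nib.Nifti1Image, space_label: str) -> VolumeGrid:
    return VolumeGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        affine=np.asarray(img.affine, dtype=float),
        space_label=space_label,
    )


def read_volume(
    path: str | Path,
    expected_grid: VolumeGrid | None = None,
    metric: str = "MD",
    subject_id: str = "",
    cohort_id: str = "",
    space_label: str = "unknown",
) -> MetricVolume:
    """Read a 3D scalar NIfTI volume.

    Raises
    ------
    FileMissingError
        If *path* does not exist.
    NotScalarVolumeError
        If the file holds anything other than one 3D scalar volume.
    GridMismatchError
        If *expected_grid* is given and the header grid differs (shape exact,
        affine entries within ``1e-4``).
    """
    path = Path(path)
    if not path.exists():
        raise FileMissingError(str(path))
    img = nib.load(path)
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        pass  # trailing singleton dimension is tolerated
    elif len(shape) != 3:
        raise NotScalarVolumeError(f"{path}: expected 3D volume, got shape {shape}")
    grid = _grid_from_header(img, space_label)
    if expected_grid is not None and not grid.matches(expected_grid):
        raise GridMismatchError(
            f"{path}: grid {grid.shape}/{grid.voxel_size_mm} does not match "
            f"expected {expected_grid.shape}/{expected_grid.voxel_size_mm}"
        )
    data = np.asanyarray(img.dataobj, dtype=np.float32).reshape(grid.shape)
    return MetricVolume(
        grid=grid, metric=metric, data=data, subject_id=subject_id, cohort_id=cohort_id
    )


def read_mask(
    path: str | Path,
    role: str = "analysis_mask",
    expected_grid: VolumeGrid | None = None,
    space_label: str = "unknown",
) -> BinaryMask:
    """Read a binary mask; any nonzero voxel counts as inside."""
    path = Path(path)
    if not path.exists():
        raise FileMissingError(str(path))
    img = nib.load(path)
    if len(img.shape) != 3:
        raise NotScalarVolumeError(f"{path}: expected 3D mask, got shape {img.shape}")
    grid = _grid_from_header(img, space_label)
    if expected_grid is not None and not grid.matches(expected_grid):
        raise GridMismatchError(f"{path}: mask grid does not match expected grid")
    data = np.asanyarray(img.dataobj) != 0
    return BinaryMask(grid=grid, data=data, role=role)


def write_volume(volume, path: str | Path) -> None:
    """Write any grid-bearing object (MetricVolume, BinaryMask, z-maps) as NIfTI.

    Float data is stored as float32 (NaN outside the valid mask is preserved);
    boolean masks as uint8.  Round-trip through :func:`read_volume` /
    :func:`read_mask` is exact for the stored dtype.
    """
    path = Path(path)
    if not path.parent.exists():
        raise VolumeIOError(f"parent directory does not exist: {path.parent}")
    grid: VolumeGrid = volume.grid
    data = _payload_array(volume)
    if data.dtype == bool:
        arr = data.astype(np.uint8)
    else:
        arr = np.asarray(data, dtype=np.float32)
    img = nib.Nifti1Image(arr, grid.affine)
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, path)


def _payload_array(volume) -> np.ndarray:
    for attr in ("z_enh", "z", "data"):
        arr = getattr(volume, attr, None)
        if arr is not None:
            return np.asarray(arr)
    raise TypeError(f"object {type(volume).__name__} carries no voxel data")


def write_sidecar(path: str | Path, payload: dict) -> None:
    """Write a JSON sidecar next to a NIfTI file (audit trail of settings)."""
    path = Path(path)
    side = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    side = side.parent / (side.name + ".json")
    side.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def assert_common_grid(volumes: Sequence) -> VolumeGrid:
    """Return the grid shared by all inputs, or raise :class:`GridMismatchError`.

    This is the single chokepoint through which every pipeline entry passes;
    no downstream operation ever sees volumes on different grids.
    """
    vols = list(volumes)
    if not vols:
        raise ValueError("assert_common_grid requires at least one volume")
    ref = vols[0].grid
    for i, v in enumerate(vols[1:], start=1):
        if not ref.matches(v.grid):
            raise GridMismatchError(
                f"volume {i} grid {v.grid.shape} @ {v.grid.voxel_size_mm} differs "
                f"from reference {ref.shape} @ {ref.voxel_size_mm}"
            )
    return ref
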