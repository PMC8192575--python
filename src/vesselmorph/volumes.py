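"""Voxel-grid containers and NIfTI I/O.

All volumes are plain 3-D numpy arrays tied to a :class:`GridSpec` that records
the anisotropic voxel spacing in millimetres.  Voxel indices are 0-based and the
world coordinate of voxel ``(i, j, k)`` is ``index * spacing + origin``; the
affine's rotational part is ignored on read (with a warning) because all inputs
are assumed co-registered in subject space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GridSpec",
    "BinaryVolume",
    "ProbabilityVolume",
    "LabelVolume",
    "GridMismatchError",
    "load_binary",
    "load_probability",
    "load_labels",
    "save_volume",
]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Shape (voxels) and spacing (mm per axis) of a 3-D voxel grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.7, 0.7, 0.7)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """World-space size of the grid bounding box."""
        return tuple(s * n for s, n in zip(self.spacing, self.shape))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            np.arange(n) * sp + o for n, sp, o in zip(self.shape, self.spacing, self.origin)
        )

    def same_grid(self, other: "GridSpec") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def _check_shape(data: np.ndarray, grid: GridSpec) -> None:
    if data.ndim != 3 or tuple(data.shape) != grid.shape:
        raise ValueError(f"data shape {data.shape} does not match grid shape {grid.shape}")


@dataclass
class BinaryVolume:
    """A {0,1} segmentation or mask volume."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        _check_shape(data, self.grid)
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"binary volume contains values other than 0/1: {uniq[:10]}")
        self.data = data.astype(np.uint8)

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class ProbabilityVolume:
    """Voxelwise occurrence probabilities in [0, 1] (e.g. a vessel atlas)."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        _check_shape(data, self.grid)
        if data.min() < 0 or data.max() > 1:
            raise ValueError(
                f"probabilities must lie in [0,1], got range [{data.min()}, {data.max()}]"
            )
        self.data = data


@dataclass
class LabelVolume:
    """Integer region labels; 0 is background, every nonzero label is named."""

    data: np.ndarray
    grid: GridSpec
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        _check_shape(data, self.grid)
        if data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = data.astype(np.int32)
        present = set(np.unique(self.data).tolist()) - {0}
        unnamed = present - set(self.label_names)
        if unnamed:
            raise ValueError(f"labels without a name: {sorted(unnamed)}")

    def label_of(self, name: str) -> int:
        for lab, nm in self.label_names.items():
            if nm == name:
                return lab
        raise KeyError(f"no label named {name!r}")


def require_same_grid(a, b, what: str = "volumes") -> None:
    if not a.grid.same_grid(b.grid):
        raise GridMismatchError(
            f"{what} are on different grids: shape/spacing "
            f"{a.grid.shape}/{a.grid.spacing} vs {b.grid.shape}/{b.grid.spacing}"
        )


# --- NIfTI I/O ---------------------------------------------------------------

def _grid_from_img(img: nib.Nifti1Image) -> GridSpec:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(np.abs(rot), np.diag(np.abs(np.diag(rot))), atol=1e-6):
        warnings.warn(
            "NIfTI affine has a rotational component; it is ignored "
            "(volumes are assumed co-registered), only spacing and translation are used.",
            stacklevel=3,
        )
    origin = tuple(float(t) for t in affine[:3, 3])
    return GridSpec(shape=img.shape[:3], spacing=zooms, origin=origin)


def load_binary(path: str | Path) -> BinaryVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return BinaryVolume(data=(data > 0.5).astype(np.uint8), grid=_grid_from_img(img))


def load_probability(path: str | Path) -> ProbabilityVolume:
    img = nib.load(str(path))
    return ProbabilityVolume(data=np.asarray(img.dataobj, dtype=np.float64), grid=_grid_from_img(img))


def load_labels(path: str | Path, label_names: dict[int, str] | None = None) -> LabelVolume:
    img = nib.load(str(path))
    data = np.rint(np.asarray(img.dataobj)).astype(np.int32)
    if label_names is None:
        label_names = {int(l): str(int(l)) for l in np.unique(data) if l != 0}
    return LabelVolume(data=data, grid=_grid_from_img(img), label_names=label_names)


def save_volume(vol: BinaryVolume | ProbabilityVolume | LabelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI with spacing in the header (diagonal affine)."""
    grid = vol.grid
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    data = vol.data
    if data.dtype == np.uint8 or data.dtype == np.int32:
        arr = data
    else:
        arr = data.astype(np.float32)
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(grid.spacing)
    path = Path(path)
    nib.save(img, str(path))
    return path
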