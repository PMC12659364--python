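"""Voxel-grid containers shared by the whole pipeline.

A :class:`Volume` is a 3-D scalar field (Hounsfield units, or a derived
image) on a regular anisotropic grid; a :class:`BinaryMask` is an aligned
0/1 indicator grid.  Array axes are (x, y, z) with z the axial (slice)
axis; ``spacing_mm[k]`` is the physical voxel size along axis ``k`` and
``origin_mm`` the physical position of the centre of voxel (0, 0, 0).
Voxel centres therefore sit at ``origin + index * spacing`` (half-open
voxel-centre convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "BinaryMask", "load_volume", "load_mask"]


def _validate_geometry(values: np.ndarray, spacing: np.ndarray, origin: np.ndarray) -> None:
    if values.ndim != 3:
        raise ValueError(f"expected a 3-D grid, got ndim={values.ndim}")
    if spacing.shape != (3,) or origin.shape != (3,):
        raise ValueError("spacing_mm and origin_mm must be length-3 vectors")
    if not np.all(spacing > 0):
        raise ValueError(f"voxel spacing must be strictly positive, got {spacing}")


@dataclass
class Volume:
    """3-D scalar grid with physical geometry."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64)
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64)
        _validate_geometry(self.values, self.spacing_mm, self.origin_mm)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_geometry(self, other: "Volume | BinaryMask", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing_mm.copy(), self.origin_mm.copy())

    def to_nifti(self, path: str) -> None:
        affine = np.diag(np.append(self.spacing_mm, 1.0))
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), path)


@dataclass
class BinaryMask:
    """ROI indicator grid aligned to a :class:`Volume`."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.values = arr.astype(bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64)
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64)
        _validate_geometry(self.values, self.spacing_mm, self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.values.sum())

    def same_geometry(self, other: "Volume | BinaryMask", atol: float = 1e-9) -> bool:
        return Volume.same_geometry(self, other, atol)  # type: ignore[arg-type]

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.values.copy(), self.spacing_mm.copy(), self.origin_mm.copy())

    def to_nifti(self, path: str) -> None:
        affine = np.diag(np.append(self.spacing_mm, 1.0))
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.values.astype(np.uint8), affine), path)


def _load(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    affine = img.affine
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    origin = affine[:3, 3]
    return data, spacing, origin


def load_volume(path: str) -> Volume:
    data, spacing, origin = _load(path)
    return Volume(data.astype(np.float64), spacing, origin)


def load_mask(path: str) -> BinaryMask:
    data, spacing, origin = _load(path)
    return BinaryMask(data > 0.5, spacing, origin)
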