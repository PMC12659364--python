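"""Ring-ROI construction, HU-window resegmentation, and the perturbation
grid of resampling/interpolation settings.

The perturbation grid is the "original" (no resampling) setting plus the
cross product of five isotropic voxel sizes (0.50, 0.75, 1.0, 1.25,
1.5 mm) and four interpolators (trilinear, cubic B-spline, Welch
windowed sinc, nearest neighbour): 21 settings in total.  Resampling is
delegated to SimpleITK; the Welch windowed-sinc kernel uses the toolkit
default radius of 3 samples per axis, window w(d) = 1 - (d/(r+1))^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .grid import BinaryMask, Volume

__all__ = [
    "ISO_VOXEL_SIZES_MM",
    "INTERPOLATORS",
    "ImagingConfig",
    "enumerate_configs",
    "periluminal_ring",
    "resegment_hu",
    "resample",
    "resample_mask",
]

ISO_VOXEL_SIZES_MM = (0.50, 0.75, 1.0, 1.25, 1.5)
INTERPOLATORS = ("linear", "bspline3", "welch_sinc", "nearest")

_SITK_INTERP = {
    "linear": sitk.sitkLinear,
    "bspline3": sitk.sitkBSpline,
    "welch_sinc": sitk.sitkWelchWindowedSinc,
    "nearest": sitk.sitkNearestNeighbor,
}


@dataclass(frozen=True)
class ImagingConfig:
    """One perturbation setting: 'original', or an isotropic target voxel
    size plus an interpolator."""

    kind: str  # {"original", "resampled"}
    voxel_mm: float | None = None
    interpolator: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "original":
            if self.voxel_mm is not None or self.interpolator is not None:
                raise ValueError("original config takes no voxel size or interpolator")
        elif self.kind == "resampled":
            if self.voxel_mm not in ISO_VOXEL_SIZES_MM:
                raise ValueError(
                    f"voxel_mm must be one of {ISO_VOXEL_SIZES_MM}, got {self.voxel_mm}"
                )
            if self.interpolator not in INTERPOLATORS:
                raise ValueError(f"unknown interpolator {self.interpolator!r}")
        else:
            raise ValueError(f"unknown config kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == "original":
            return "original"
        return f"{self.voxel_mm:.2f}mm_{self.interpolator}"

    def to_dict(self) -> dict:
        return {"kind": self.kind, "voxel_mm": self.voxel_mm, "interpolator": self.interpolator}

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingConfig":
        return cls(kind=d["kind"], voxel_mm=d.get("voxel_mm"), interpolator=d.get("interpolator"))


def enumerate_configs() -> list[ImagingConfig]:
    """The full perturbation grid, in fixed order: original first, then
    voxel sizes ascending, interpolators in registry order within each."""
    configs = [ImagingConfig(kind="original")]
    for voxel in ISO_VOXEL_SIZES_MM:
        for interp in INTERPOLATORS:
            configs.append(ImagingConfig(kind="resampled", voxel_mm=voxel, interpolator=interp))
    return configs


# ---------------------------------------------------------------------------
# ring ROI and resegmentation
# ---------------------------------------------------------------------------

def periluminal_ring(lumen: BinaryMask, width_vox: int = 2) -> BinaryMask:
    """Ring of voxels at 3-D Euclidean distance (in voxel units) in
    (0, width_vox] from the lumen; disjoint from the lumen, clipped at the
    grid boundary.

    "Two pixels" is interpreted on the native grid: distances are in
    voxel units, not millimetres, so the ring tracks the vessel wall at
    the resolution of the mask it is built from.
    """
    if width_vox < 1:
        raise ValueError(f"ring width must be >= 1 voxel, got {width_vox}")
    if not lumen.values.any():
        return BinaryMask(
            np.zeros(lumen.shape, dtype=bool), lumen.spacing_mm.copy(), lumen.origin_mm.copy()
        )
    # exact Euclidean distance (voxel units) of each exterior voxel to the lumen
    dist = ndimage.distance_transform_edt(~lumen.values)
    ring = (dist > 0) & (dist <= width_vox)
    return BinaryMask(ring, lumen.spacing_mm.copy(), lumen.origin_mm.copy())


def resegment_hu(
    vol: Volume, roi: BinaryMask, lo: float = -170.0, hi: float = 200.0
) -> BinaryMask:
    """Drop ROI voxels whose intensity falls outside [lo, hi] (inclusive).

    This is resegmentation — voxel exclusion — not intensity clamping:
    bright lumen/calcium voxels are removed from the ROI entirely so they
    cannot contaminate periluminal statistics.
    """
    if lo >= hi:
        raise ValueError(f"window bounds must satisfy lo < hi, got [{lo}, {hi}]")
    if not vol.same_geometry(roi):
        raise ValueError("volume and ROI geometries differ")
    keep = roi.values & (vol.values >= lo) & (vol.values <= hi)
    return BinaryMask(keep, roi.spacing_mm.copy(), roi.origin_mm.copy())


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _to_sitk(values: np.ndarray, spacing: np.ndarray, origin: np.ndarray) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.T))  # sitk wants (z, y, x)
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _target_grid(shape: tuple[int, ...], spacing: np.ndarray, voxel_mm: float) -> list[int]:
    extent = np.asarray(shape) * spacing
    size = [int(np.ceil(e / voxel_mm - 1e-9)) for e in extent]
    if any(s < 1 for s in size):
        raise ValueError("target extent collapses to zero voxels")
    return size


_SINC_RADIUS = 3  # samples per axis; Welch window w(d) = 1 - (d / (r + 1))^2


def _welch_axis_weights(n_in: int, n_out: int, step: float) -> np.ndarray:
    """Row-normalized 1-D Welch-windowed-sinc interpolation matrix.

    Rows are normalized so the kernel has unit DC gain (constants are
    reproduced exactly); out-of-range taps clamp to the edge sample
    (nearest-neighbour extrapolation, matching the other interpolators).
    """
    centers = np.arange(n_out) * step  # output voxel centres in input index units
    taps = np.arange(-_SINC_RADIUS + 1, _SINC_RADIUS + 1)
    j = np.floor(centers)[:, None].astype(int) + taps[None, :]
    d = centers[:, None] - j
    w = np.sinc(d) * (1.0 - (d / (_SINC_RADIUS + 1)) ** 2)
    w[np.abs(d) > _SINC_RADIUS] = 0.0
    w /= w.sum(axis=1, keepdims=True)
    jc = np.clip(j, 0, n_in - 1)
    mat = np.zeros((n_out, n_in))
    np.add.at(mat, (np.repeat(np.arange(n_out), len(taps)), jc.ravel()), w.ravel())
    return mat


def _welch_sinc_resample(values: np.ndarray, spacing: np.ndarray, voxel_mm: float,
                         size: list[int]) -> np.ndarray:
    out = values
    for axis in range(3):
        w = _welch_axis_weights(values.shape[axis], size[axis], voxel_mm / spacing[axis])
        out = np.moveaxis(np.tensordot(w, np.moveaxis(out, axis, 0), axes=(1, 0)), 0, axis)
    return out


def _resample_array(
    values: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray,
    voxel_mm: float,
    interpolator: str,
) -> np.ndarray:
    if interpolator == "welch_sinc":
        size = _target_grid(values.shape, spacing, voxel_mm)
        return _welch_sinc_resample(np.asarray(values, dtype=np.float64), spacing,
                                    voxel_mm, size)
    img = _to_sitk(values, spacing, origin)
    size = _target_grid(values.shape, spacing, voxel_mm)
    rf = sitk.ResampleImageFilter()
    rf.SetOutputSpacing((voxel_mm,) * 3)
    rf.SetSize(size)
    rf.SetOutputOrigin(tuple(float(o) for o in origin))
    rf.SetOutputDirection(img.GetDirection())
    rf.SetInterpolator(_SITK_INTERP[interpolator])
    # voxel centres near the boundary may fall outside the input's centre
    # lattice; extend by nearest neighbour rather than padding with a constant
    if hasattr(rf, "SetUseNearestNeighborExtrapolator"):
        rf.SetUseNearestNeighborExtrapolator(True)
    out = rf.Execute(img)
    return sitk.GetArrayFromImage(out).T


def resample(vol: Volume, cfg: ImagingConfig) -> Volume:
    """Resample onto an isotropic grid spanning the same physical extent,
    voxel-centre aligned to the input origin.  'original' is the identity."""
    if cfg.kind == "original":
        return vol.copy()
    out = _resample_array(
        vol.values, vol.spacing_mm, vol.origin_mm, cfg.voxel_mm, cfg.interpolator
    )
    return Volume(out, np.full(3, cfg.voxel_mm), vol.origin_mm.copy())


def resample_mask(mask: BinaryMask, cfg: ImagingConfig) -> BinaryMask:
    """Resample a binary mask; always nearest neighbour, output stays 0/1."""
    if cfg.kind == "original":
        return mask.copy()
    out = _resample_array(
        mask.values.astype(np.uint8), mask.spacing_mm, mask.origin_mm, cfg.voxel_mm, "nearest"
    )
    return BinaryMask(out > 0, np.full(3, cfg.voxel_mm), mask.origin_mm.copy())
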