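"""Natively implemented radiomic features over derived images.

Families: first-order intensity statistics, grey-level co-occurrence
(GLCM), neighbourhood grey-tone difference (NGTDM), and 3-D shape.
Derived images: original, Laplacian-of-Gaussian at sigma = 2 mm,
gradient magnitude, and signed square root.  Feature names follow the
``<filter>_<family>_<Feature>`` convention (e.g.
``squareroot_ngtdm_Strength``); shape features are geometry-only and
carry the ``original_shape_`` prefix.

Texture definitions
-------------------
Grey levels are integers 1..Ng from fixed-width binning anchored at the
lower HU window bound (original images) or the ROI minimum (derived
images, whose values are not in HU).  GLCM uses symmetric co-occurrence
at distance 1 over the 13 unique 3-D directions, normalized per
direction, features averaged over directions with at least one
co-occurring pair.  NGTDM uses the valid 26-neighbourhood mean: for each
level i present in the ROI, s_i sums |i - neighbourhood mean| over the
ROI voxels of level i (voxels with no ROI neighbour are excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .grid import BinaryMask, Volume
from .image_ops import ImagingConfig, periluminal_ring, resample, resample_mask, resegment_hu

log = logging.getLogger(__name__)

__all__ = [
    "FILTERS",
    "DiscretizationSpec",
    "ExtractionSpec",
    "apply_filter",
    "discretize",
    "first_order",
    "glcm_features",
    "ngtdm_features",
    "shape_features",
    "extract_all",
    "feature_names",
]

FILTERS = ("original", "log_sigma_2_0_mm", "gradient", "squareroot")

_EPS = 1e-12
_COARSENESS_CAP = 1.0 / _EPS  # documented maximum for a homogeneous ROI

def _unique_directions() -> list[tuple[int, int, int]]:
    """13 unique distance-1 directions (half of the 26-neighbourhood)."""
    dirs = []
    for dx in (0, 1, -1):
        for dy in (0, 1, -1):
            for dz in (0, 1, -1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if tuple(-c for c in d) in dirs:
                    continue
                dirs.append(d)
    return dirs


_DIRECTIONS = _unique_directions()
assert len(_DIRECTIONS) == 13


# ---------------------------------------------------------------------------
# derived images
# ---------------------------------------------------------------------------

def apply_filter(vol: Volume, filter_name: str) -> Volume:
    """Derived image: identity, spacing-aware LoG (sigma = 2 mm),
    spacing-aware gradient magnitude, or signed square root."""
    v = vol.values
    spacing = vol.spacing_mm
    if filter_name == "original":
        return vol.copy()
    if filter_name == "log_sigma_2_0_mm":
        sigma_vox = 2.0 / spacing
        smoothed = ndimage.gaussian_filter(v, sigma=sigma_vox, mode="nearest")
        lap = np.zeros_like(smoothed)
        for axis in range(3):
            g = np.gradient(smoothed, spacing[axis], axis=axis)
            lap += np.gradient(g, spacing[axis], axis=axis)
        return Volume(lap, spacing.copy(), vol.origin_mm.copy())
    if filter_name == "gradient":
        grads = np.gradient(v, *spacing)
        mag = np.sqrt(sum(g * g for g in grads))
        return Volume(mag, spacing.copy(), vol.origin_mm.copy())
    if filter_name == "squareroot":
        return Volume(np.sign(v) * np.sqrt(np.abs(v)), spacing.copy(), vol.origin_mm.copy())
    raise ValueError(f"unknown filter {filter_name!r}; expected one of {FILTERS}")


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizationSpec:
    """Fixed-bin-width grey-level discretization.

    Original images anchor at the lower HU window bound so bins are
    comparable across subjects; derived images (not in HU) anchor at the
    ROI minimum and use a per-filter width chosen to give a usable number
    of grey levels on each value scale.
    """

    bin_width: float = 25.0
    anchor: float = -170.0
    filter_bin_widths: dict = field(
        default_factory=lambda: {
            "original": 25.0,
            "log_sigma_2_0_mm": 25.0,
            "gradient": 25.0,
            "squareroot": 1.0,
        }
    )

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or any(w <= 0 for w in self.filter_bin_widths.values()):
            raise ValueError("bin widths must be positive")

    def width_for(self, filter_name: str) -> float:
        return float(self.filter_bin_widths.get(filter_name, self.bin_width))


def discretize(
    vol: Volume,
    roi: BinaryMask,
    spec: DiscretizationSpec | None = None,
    filter_name: str = "original",
) -> tuple[np.ndarray, int]:
    """Map ROI voxels to grey levels 1..Ng; 0 outside the ROI.

    Level of value v is floor((v - anchor) / width) + 1.  Original
    images anchor at ``spec.anchor``; derived images at the ROI minimum.
    """
    spec = spec or DiscretizationSpec()
    if not roi.values.any():
        raise ValueError("cannot discretize an empty ROI")
    width = spec.width_for(filter_name)
    vals = vol.values[roi.values]
    anchor = spec.anchor if filter_name == "original" else float(vals.min())
    lv = np.floor((vals - anchor) / width).astype(np.int64) + 1
    lv = np.maximum(lv, 1)
    levels = np.zeros(vol.shape, dtype=np.int64)
    levels[roi.values] = lv
    return levels, int(lv.max())


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def first_order(
    vol: Volume,
    roi: BinaryMask,
    spec: DiscretizationSpec | None = None,
    filter_name: str = "original",
) -> dict[str, float]:
    """Intensity statistics on the raw ROI values; Entropy/Uniformity on
    the discretized grey-level probabilities (entropy in bits).

    Central moments use the population (1/N) convention.  For a constant
    or single-voxel ROI, skewness and kurtosis are defined as 0.
    """
    if not roi.values.any():
        raise ValueError("first-order statistics need a nonempty ROI")
    v = vol.values[roi.values].astype(np.float64)
    n = v.size
    mean = float(v.mean())
    centered = v - mean
    var = float(np.mean(centered**2))
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / sd**4)
    else:
        if n == 1:
            log.debug("single-voxel ROI: skewness/kurtosis defined as 0")
        skew = kurt = 0.0

    levels_grid, ng = discretize(vol, roi, spec, filter_name)
    levels_flat = levels_grid[roi.values]
    counts = np.bincount(levels_flat, minlength=ng + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p * p).sum())

    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Minimum": float(v.min()),
        "Maximum": float(v.max()),
        "Range": float(v.max() - v.min()),
        "Energy": float((v * v).sum()),
        "RootMeanSquared": float(np.sqrt(np.mean(v * v))),
        "MeanAbsoluteDeviation": float(np.abs(centered).mean()),
        "Entropy": entropy,
        "Uniformity": uniformity,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _shift_pairs(levels: np.ndarray, roi: np.ndarray, d: tuple[int, int, int]):
    """Index arrays (i, j) of co-occurring grey levels along direction d."""
    slc_a = []
    slc_b = []
    for off, size in zip(d, levels.shape):
        if off == 0:
            slc_a.append(slice(None))
            slc_b.append(slice(None))
        elif off > 0:
            slc_a.append(slice(0, size - off))
            slc_b.append(slice(off, size))
        else:
            slc_a.append(slice(-off, size))
            slc_b.append(slice(0, size + off))
    a, b = levels[tuple(slc_a)], levels[tuple(slc_b)]
    valid = roi[tuple(slc_a)] & roi[tuple(slc_b)]
    return a[valid], b[valid]


def glcm_features(levels: np.ndarray, roi: BinaryMask, ng: int) -> dict[str, float]:
    """GLCM features at distance 1, averaged over the 13 unique 3-D
    directions that contain at least one co-occurring ROI pair.

    Matrices are symmetric and normalized per direction.  Correlation is
    defined as 1 when the marginal variance is zero (degenerate
    single-level direction).  If no direction has a valid pair, all
    features are 0.
    """
    mask = roi.values
    idx = np.arange(1, ng + 1, dtype=np.float64)
    ii = idx[:, None] * np.ones((1, ng))
    jj = ii.T
    diff2 = (ii - jj) ** 2

    acc: dict[str, list[float]] = {k: [] for k in
        ("Contrast", "Correlation", "InverseVariance", "Idm", "JointEntropy")}
    for d in _DIRECTIONS:
        a, b = _shift_pairs(levels, mask, d)
        if a.size == 0:
            continue
        counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng).reshape(ng, ng)
        counts = counts + counts.T  # symmetric
        p = counts / counts.sum()

        contrast = float((p * diff2).sum())
        off_diag = diff2 > 0
        inv_var = float((p[off_diag] / diff2[off_diag]).sum())
        idm = float((p / (1.0 + diff2)).sum())
        pz = p[p > 0]
        joint_entropy = float(-(pz * np.log2(pz)).sum())
        px = p.sum(axis=1)
        mu = float((idx * px).sum())
        var = float(((idx - mu) ** 2 * px).sum())
        if var > 0:
            corr = float(((ii - mu) * (jj - mu) * p).sum() / var)
        else:
            corr = 1.0
        acc["Contrast"].append(contrast)
        acc["Correlation"].append(corr)
        acc["InverseVariance"].append(inv_var)
        acc["Idm"].append(idm)
        acc["JointEntropy"].append(joint_entropy)

    if not acc["Contrast"]:
        log.debug("GLCM: no valid co-occurring pairs in any direction; features set to 0")
        return {k: 0.0 for k in acc}
    return {k: float(np.mean(vals)) for k, vals in acc.items()}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(levels: np.ndarray, roi: BinaryMask, ng: int) -> dict[str, float]:
    """Neighbourhood grey-tone difference features.

    For each ROI voxel with at least one ROI voxel in its
    26-neighbourhood, the absolute difference between its level and the
    neighbourhood mean contributes to s_i of its level i.
    """
    mask = roi.values
    if not mask.any():
        raise ValueError("NGTDM needs a nonempty ROI")
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    lv = levels.astype(np.float64) * mask
    nbr_sum = ndimage.correlate(lv, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = mask & (nbr_cnt > 0.5)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("NGTDM: no ROI voxel has a valid neighbourhood")
    lvl_valid = levels[valid]
    mean_nbr = nbr_sum[valid] / nbr_cnt[valid]
    diffs = np.abs(lvl_valid - mean_nbr)

    n_i = np.bincount(lvl_valid, minlength=ng + 1)[1:].astype(np.float64)
    s_i = np.bincount(lvl_valid, weights=diffs, minlength=ng + 1)[1:]
    p_i = n_i / n
    present = p_i > 0
    idx = np.arange(1, ng + 1, dtype=np.float64)

    ip = idx[present]
    pp = p_i[present]
    sp = s_i[present]
    di = ip[:, None] - ip[None, :]

    sum_ps = float((p_i * s_i).sum())
    sum_s = float(s_i.sum())
    ngp = int(present.sum())

    coarseness = min(1.0 / max(sum_ps, _EPS), _COARSENESS_CAP)
    if ngp > 1:
        contrast = float(
            (pp[:, None] * pp[None, :] * di**2).sum() / (ngp * (ngp - 1)) * (sum_s / n)
        )
        denom_busy = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = sum_ps / denom_busy if denom_busy > 0 else 0.0
        complexity = float(
            (
                np.abs(di)
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / (pp[:, None] + pp[None, :])
            ).sum()
            / n
        )
        strength = float(((pp[:, None] + pp[None, :]) * di**2).sum()) / (_EPS + sum_s)
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def _max_diameter(coords_mm: np.ndarray) -> float:
    if len(coords_mm) < 2:
        return 0.0
    pts = coords_mm
    if len(pts) > 400:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets fall back to all points
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def shape_features(roi: BinaryMask) -> dict[str, float]:
    """Voxel-counted volume, face-counted surface area, sphericity, and
    maximum 3-D diameter (voxel-centre pairwise distance)."""
    mask = roi.values
    if not mask.any():
        raise ValueError("shape features need a nonempty mask")
    spacing = roi.spacing_mm
    n = int(mask.sum())
    volume = n * float(np.prod(spacing))

    area = 0.0
    exposed_any = np.zeros_like(mask)
    for axis in range(3):
        face = float(np.prod(np.delete(spacing, axis)))
        m = np.moveaxis(mask, axis, 0)
        interior = m[1:] != m[:-1]
        n_faces = int(interior.sum()) + int(m[0].sum()) + int(m[-1].sum())
        area += n_faces * face
        exp = np.zeros_like(m)
        exp[1:] |= interior & m[1:]
        exp[:-1] |= interior & m[:-1]
        exp[0] |= m[0]
        exp[-1] |= m[-1]
        exposed_any |= np.moveaxis(exp, 0, axis)

    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)
    surf_coords = np.argwhere(exposed_any) * spacing
    return {
        "VoxelVolume": volume,
        "SurfaceArea": area,
        "Sphericity": sphericity,
        "Maximum3DDiameter": _max_diameter(surf_coords),
    }


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

_FIRST_ORDER_NAMES = (
    "Mean", "Variance", "Skewness", "Kurtosis", "Minimum", "Maximum", "Range",
    "Energy", "RootMeanSquared", "MeanAbsoluteDeviation", "Entropy", "Uniformity",
)
_GLCM_NAMES = ("Contrast", "Correlation", "InverseVariance", "Idm", "JointEntropy")
_NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
_SHAPE_NAMES = ("VoxelVolume", "SurfaceArea", "Sphericity", "Maximum3DDiameter")


@dataclass
class ExtractionSpec:
    """Parameters of one feature-extraction run."""

    ring_width_vox: int = 2
    hu_window: tuple[float, float] = (-170.0, 200.0)
    discretization: DiscretizationSpec = field(default_factory=DiscretizationSpec)
    filters: tuple[str, ...] = FILTERS

    def to_dict(self) -> dict:
        return {
            "ring_width_vox": self.ring_width_vox,
            "hu_window": list(self.hu_window),
            "bin_width": self.discretization.bin_width,
            "anchor": self.discretization.anchor,
            "filter_bin_widths": dict(self.discretization.filter_bin_widths),
            "filters": list(self.filters),
        }


def feature_names(spec: ExtractionSpec | None = None) -> list[str]:
    """The fixed, ordered schema of one extracted feature vector."""
    spec = spec or ExtractionSpec()
    names = []
    for filt in spec.filters:
        names += [f"{filt}_firstorder_{n}" for n in _FIRST_ORDER_NAMES]
        names += [f"{filt}_glcm_{n}" for n in _GLCM_NAMES]
        names += [f"{filt}_ngtdm_{n}" for n in _NGTDM_NAMES]
    names += [f"original_shape_{n}" for n in _SHAPE_NAMES]
    return names


def extract_all(
    vol: Volume,
    lumen_mask: BinaryMask,
    cfg: ImagingConfig,
    spec: ExtractionSpec | None = None,
) -> pd.Series:
    """Resample -> periluminal ring -> HU resegmentation -> features for
    every filter x family; shape features come from the original-geometry
    ring only (they describe the segmentation, not the resampled image).

    Returns a named Series following :func:`feature_names`; if the HU
    window empties the ROI at this configuration, all values are NaN and
    the subject should be flagged by the caller.
    """
    spec = spec or ExtractionSpec()
    lo, hi = spec.hu_window
    names = feature_names(spec)

    rvol = resample(vol, cfg)
    rmask = resample_mask(lumen_mask, cfg)
    ring = periluminal_ring(rmask, spec.ring_width_vox)
    roi = resegment_hu(rvol, ring, lo, hi)
    if roi.count() == 0:
        log.warning("ROI empty after resegmentation at config %s; features set missing", cfg.name)
        return pd.Series(np.nan, index=names)

    values: dict[str, float] = {}
    for filt in spec.filters:
        fvol = apply_filter(rvol, filt)
        fo = first_order(fvol, roi, spec.discretization, filt)
        for k in _FIRST_ORDER_NAMES:
            values[f"{filt}_firstorder_{k}"] = fo[k]
        levels, ng = discretize(fvol, roi, spec.discretization, filt)
        gl = glcm_features(levels, roi, ng)
        for k in _GLCM_NAMES:
            values[f"{filt}_glcm_{k}"] = gl[k]
        ng_feats = ngtdm_features(levels, roi, ng)
        for k in _NGTDM_NAMES:
            values[f"{filt}_ngtdm_{k}"] = ng_feats[k]

    native_ring = periluminal_ring(lumen_mask, spec.ring_width_vox)
    native_roi = resegment_hu(vol, native_ring, lo, hi)
    shape_src = native_roi if native_roi.count() > 0 else native_ring
    sh = shape_features(shape_src)
    for k in _SHAPE_NAMES:
        values[f"original_shape_{k}"] = sh[k]

    return pd.Series([values[n] for n in names], index=names)
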