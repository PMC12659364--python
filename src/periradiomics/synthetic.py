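"""Synthetic coronary vessel phantoms and table-level cohorts.

Every downstream stage of the pipeline (ring-ROI extraction, the
stability screen, feature reduction, the classifier harness) is testable
against these generators, whose ground truth is known by construction.

The image phantom is one contrast-opacified vessel segment: a tube of
lumen attenuation (~400 HU) around a parametric centerline, wrapped in a
periluminal fat sheath (~-80 HU) inside soft-tissue background (~40 HU).
Lumen narrowing (stenosis) is modelled as a smooth radial indentation
whose displaced volume is filled with soft plaque (~60 HU); calcified
plaque is modelled as Gaussian attenuation blobs peaking at 130-1000 HU.
Acquisition noise is additive Gaussian.  Ground-truth calcium burden is
scored with the per-slice Agatston technique and binned into the four
standard categories; ground-truth stenosis is the percent diameter
reduction of the noise-free lumen geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import BinaryMask, Volume

__all__ = [
    "SEGMENTS",
    "STENOSIS4_LABELS",
    "STENOSIS3_LABELS",
    "PhantomSpec",
    "GroundTruth",
    "CohortTableSpec",
    "FeatureTable",
    "generate_vessel_phantom",
    "agatston_score",
    "cac_category",
    "stenosis_category",
    "generate_feature_cohort",
]

#: The five major coronary segments carried as ground-truth labels.
SEGMENTS = ("LMA", "LCX", "LAD", "pRCA", "mRCA")

#: Four-way stenosis grading: <10%, 10-49%, 50-70%, >70% diameter reduction.
STENOSIS4_LABELS = ("none", "mild", "moderate", "severe")

#: Three-way grading: <10%, 10-49%, >=50% (moderate and severe merged).
STENOSIS3_LABELS = ("none", "mild", "significant")


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Full description of one synthetic vessel acquisition.

    ``stenoses`` is a list of ``(arc_position, severity, length_mm)``
    tuples: arc position is the fractional position 0..1 along the
    centerline, severity the peak fractional diameter reduction (0-0.9),
    length the longitudinal extent of the narrowing.  ``plaques`` is a
    list of ``(center_mm, radius_mm, peak_hu)`` with peak_hu in
    [130, 1000].
    """

    grid_shape: tuple[int, int, int] = (36, 36, 14)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 3.0)
    centerline: Sequence[Sequence[float]] | None = None
    lumen_radius_mm: float = 1.6
    stenoses: list[tuple[float, float, float]] = field(default_factory=list)
    plaques: list[tuple[tuple[float, float, float], float, float]] = field(default_factory=list)
    background_hu: float = 40.0
    fat_hu: float = -80.0
    lumen_hu: float = 400.0
    plaque_fill_hu: float = 60.0
    fat_thickness_mm: float = 3.0
    noise_sd_hu: float = 0.0
    seed: int = 0
    segment_id: str = "LAD"

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise ValueError(f"invalid grid_shape {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing_mm}")
        if self.lumen_radius_mm <= 0:
            raise ValueError("lumen radius must be positive")
        for pos, sev, length in self.stenoses:
            if not (0.0 <= sev <= 0.9):
                raise ValueError(f"stenosis severity must lie in [0, 0.9], got {sev}")
            if length <= 0 or not (0.0 <= pos <= 1.0):
                raise ValueError("stenosis arc position must be in [0,1] and length positive")
        for _, radius, peak in self.plaques:
            if peak < 130.0:
                raise ValueError(f"calcified plaque peak must be >= 130 HU, got {peak}")
            if radius <= 0:
                raise ValueError("plaque radius must be positive")
        if self.noise_sd_hu < 0:
            raise ValueError("noise SD must be non-negative")
        if self.segment_id not in SEGMENTS:
            raise ValueError(f"segment_id must be one of {SEGMENTS}")


@dataclass
class GroundTruth:
    """Noise-free labels for one phantom."""

    agatston_au: float
    cac_class: int
    max_stenosis_pct: float
    stenosis_class4: str
    stenosis_class3: str
    segment_id: str

    def to_dict(self) -> dict:
        return {
            "agatston_au": self.agatston_au,
            "cac_class": self.cac_class,
            "max_stenosis_pct": self.max_stenosis_pct,
            "stenosis_class4": self.stenosis_class4,
            "stenosis_class3": self.stenosis_class3,
            "segment_id": self.segment_id,
        }


# ---------------------------------------------------------------------------
# category maps (total, monotone step functions)
# ---------------------------------------------------------------------------

def cac_category(score: float) -> int:
    """Bin an Agatston score (AU) into the four calcium categories.

    Bins: [0, 10] -> 0, (10, 100] -> 1, (100, 400) -> 2, >= 400 -> 3.
    """
    if score < 0:
        raise ValueError(f"Agatston score cannot be negative, got {score}")
    if score <= 10:
        return 0
    if score <= 100:
        return 1
    if score < 400:
        return 2
    return 3


def stenosis_category(pct: float, scheme: str = "four") -> str:
    """Grade percent diameter stenosis.

    ``four``: <10 none, 10-49 mild, 50-70 moderate, >70 severe.
    ``three``: <10 none, 10-49 mild, >=50 significant.
    """
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"stenosis percent must lie in [0, 100], got {pct}")
    if scheme == "four":
        if pct < 10:
            return "none"
        if pct < 50:
            return "mild"
        if pct <= 70:
            return "moderate"
        return "severe"
    if scheme == "three":
        if pct < 10:
            return "none"
        if pct < 50:
            return "mild"
        return "significant"
    raise ValueError(f"unknown scheme {scheme!r}; expected 'four' or 'three'")


# ---------------------------------------------------------------------------
# Agatston scoring
# ---------------------------------------------------------------------------

def _agatston_weight(max_hu: float) -> int:
    # density weight by lesion peak attenuation: 130-199 -> 1, 200-299 -> 2,
    # 300-399 -> 3, >=400 -> 4
    return min(4, int(max_hu // 100))


def agatston_score(
    vol: Volume,
    calc_region: BinaryMask,
    threshold_hu: float = 130.0,
    min_area_mm2: float = 1.0,
) -> float:
    """Agatston calcium score over ``calc_region``, axial slices = axis 2.

    Per slice, 8-connected lesions of voxels >= 130 HU with in-plane area
    >= 1 mm^2 score area(mm^2) x density weight (1-4 by lesion max HU);
    slice scores are summed and scaled by slice thickness / 3 mm.
    """
    if not vol.same_geometry(calc_region):
        raise ValueError("volume and calcification region geometries differ")
    sx, sy, sz = vol.spacing_mm
    pixel_area = sx * sy
    if pixel_area <= 0 or sz <= 0:
        raise ValueError("slice has zero physical extent")
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity in-plane
    total = 0.0
    candidates = calc_region.values & (vol.values >= threshold_hu)
    for k in range(vol.shape[2]):
        sl = candidates[:, :, k]
        if not sl.any():
            continue
        labels, n_lesions = ndimage.label(sl, structure=structure)
        hu_slice = vol.values[:, :, k]
        for lesion in range(1, n_lesions + 1):
            where = labels == lesion
            area = where.sum() * pixel_area
            if area < min_area_mm2 - 1e-12:
                continue
            total += area * _agatston_weight(float(hu_slice[where].max()))
    return total * sz / 3.0


# ---------------------------------------------------------------------------
# phantom rasterization
# ---------------------------------------------------------------------------

def _default_centerline(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    cx, cy = (nx - 1) * sx / 2.0, (ny - 1) * sy / 2.0
    return np.array([[cx, cy, 0.0], [cx, cy, (nz - 1) * sz]])


def _densify_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~step spacing; returns (samples, arc fraction)."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = float(seg_len.sum())
    if total <= 0:
        raise ValueError("degenerate centerline (zero length)")
    samples = [points[0]]
    arcs = [0.0]
    acc = 0.0
    for p0, d, ln in zip(points[:-1], seg, seg_len):
        if ln == 0:
            continue
        n = max(1, int(math.ceil(ln / step)))
        for i in range(1, n + 1):
            samples.append(p0 + d * (i / n))
            arcs.append(acc + ln * (i / n))
        acc += ln
    return np.asarray(samples), np.asarray(arcs) / total


def _radius_profile(spec: PhantomSpec, t: np.ndarray, total_len: float) -> np.ndarray:
    """Lumen radius at arc fraction t: baseline modulated by stenosis bumps."""
    bump = np.zeros_like(t)
    for pos, sev, length in spec.stenoses:
        ds = (t - pos) * total_len
        inside = np.abs(ds) <= length / 2.0
        bump[inside] += sev * 0.5 * (1.0 + np.cos(2.0 * np.pi * ds[inside] / length))
    bump = np.clip(bump, 0.0, 0.95)
    return spec.lumen_radius_mm * (1.0 - bump)


def generate_vessel_phantom(spec: PhantomSpec) -> tuple[Volume, BinaryMask, GroundTruth]:
    """Rasterize one phantom; ground truth is computed noise-free."""
    nx, ny, nz = (int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    points = (
        np.asarray(spec.centerline, dtype=float)
        if spec.centerline is not None
        else _default_centerline(spec)
    )
    step = float(min(spacing)) / 4.0
    samples, t_samples = _densify_polyline(points, step)
    seg_len = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total_len = float(seg_len.sum())

    # voxel centres in mm (origin at zero)
    idx = np.indices((nx, ny, nz)).reshape(3, -1).T
    centers = idx * spacing

    tree = cKDTree(samples)
    dist, nearest = tree.query(centers, workers=-1)
    dist = dist.reshape(nx, ny, nz)
    t_vox = t_samples[nearest].reshape(nx, ny, nz)

    radius_vox = _radius_profile(spec, t_vox, total_len)
    lumen = dist <= radius_vox
    if not lumen.any():
        raise ValueError("grid too small to contain the tube: empty lumen")
    # The tube may exit through the axial end faces (a vessel passes through
    # the field of view) but must not be cut by the lateral boundaries.
    if lumen[0, :, :].any() or lumen[-1, :, :].any() or lumen[:, 0, :].any() or lumen[:, -1, :].any():
        raise ValueError("grid too small to contain the tube: lumen touches lateral boundary")

    r0 = spec.lumen_radius_mm
    hu = np.full((nx, ny, nz), spec.background_hu, dtype=np.float64)
    hu[(dist > r0) & (dist <= r0 + spec.fat_thickness_mm)] = spec.fat_hu
    # soft plaque fills the space vacated by the narrowed lumen
    hu[(dist > radius_vox) & (dist <= r0)] = spec.plaque_fill_hu
    hu[lumen] = spec.lumen_hu

    for center, radius, peak in spec.plaques:
        d2 = ((centers - np.asarray(center, dtype=float)) ** 2).sum(axis=1).reshape(nx, ny, nz)
        sigma = radius / 2.0
        support = d2 <= (2.0 * radius) ** 2
        blob = peak * np.exp(-d2[support] / (2.0 * sigma * sigma))
        hu[support] = np.maximum(hu[support], blob)

    clean = Volume(hu, spacing)
    lumen_mask = BinaryMask(lumen, spacing)
    calc_region = BinaryMask(~lumen, spacing)
    score = agatston_score(clean, calc_region)

    radius_dense = _radius_profile(spec, t_samples, total_len)
    max_sten = float((1.0 - radius_dense.min() / r0) * 100.0)
    truth = GroundTruth(
        agatston_au=score,
        cac_class=cac_category(score),
        max_stenosis_pct=max_sten,
        stenosis_class4=stenosis_category(max_sten, "four"),
        stenosis_class3=stenosis_category(max_sten, "three"),
        segment_id=spec.segment_id,
    )

    values = hu
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        values = hu + rng.normal(0.0, spec.noise_sd_hu, size=hu.shape)
    return Volume(values, spacing), lumen_mask, truth


# ---------------------------------------------------------------------------
# table-level cohorts with planted structure
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects x named-features matrix with labels and covariates.

    ``per_config`` (when present) stacks the same features observed under
    each imaging configuration: shape (n_configs, n_subjects, n_features)
    with configuration 0 the unperturbed/original setting.
    """

    features: pd.DataFrame
    labels: pd.Series
    covariates: pd.DataFrame | None = None
    per_config: np.ndarray | None = None
    config_names: list[str] | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def to_csv(self, path: str) -> None:
        out = self.features.copy()
        out["label"] = self.labels.values
        if self.covariates is not None:
            for c in self.covariates.columns:
                out[c] = self.covariates[c].values
        out.to_csv(path, index=False)


@dataclass
class CohortTableSpec:
    """Planted-structure cohort: class shifts, correlation blocks, and
    configuration-dependent (unstable) features."""

    n_subjects: int = 100
    n_features: int = 20
    informative: list[tuple[int, tuple[float, ...]]] = field(default_factory=list)
    corr_blocks: list[tuple[Sequence[int], float]] = field(default_factory=list)
    unstable_set: list[int] = field(default_factory=list)
    class_priors: tuple[float, ...] = (0.5, 0.5)
    clinical_covariates: dict = field(default_factory=dict)
    missing_rate: float = 0.0
    n_configs: int = 1
    unstable_sd: float = 0.30
    stable_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.class_priors), 1.0, abs_tol=1e-9):
            raise ValueError(f"class priors must sum to 1, got {self.class_priors}")
        for idxs, rho in self.corr_blocks:
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
            if any(i >= self.n_features or i < 0 for i in idxs):
                raise ValueError("correlation block index out of range")
        for i, shifts in self.informative:
            if not (0 <= i < self.n_features):
                raise ValueError(f"informative feature index {i} out of range")
            if len(shifts) != len(self.class_priors):
                raise ValueError("per-class shifts must match the number of classes")
        if any(i >= self.n_features or i < 0 for i in self.unstable_set):
            raise ValueError("unstable feature index out of range")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing rate must lie in [0, 1)")


def _equicorrelated(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    if k == 1 or rho == 0.0:
        return rng.standard_normal((n, k))
    if rho == 1.0:
        z = rng.standard_normal(n)
        return np.tile(z[:, None], (1, k))
    if rho < -1.0 / (k - 1) + 1e-12 and k > 2:
        raise ValueError(f"equicorrelation rho={rho} infeasible for block of size {k}")
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((n, k)) @ chol.T


def _draw_covariate(rng: np.random.Generator, dist: tuple, n: int) -> tuple[np.ndarray, bool]:
    """Returns (values, is_continuous)."""
    kind = dist[0]
    if kind == "normal":
        return rng.normal(dist[1], dist[2], size=n), True
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=n), True
    if kind == "bernoulli":
        return rng.binomial(1, dist[1], size=n).astype(float), False
    raise ValueError(f"unknown covariate distribution {kind!r}")


def generate_feature_cohort(spec: CohortTableSpec) -> FeatureTable:
    """Draw a cohort with planted class shifts, correlation blocks, and
    per-configuration multiplicative perturbation of the unstable set.

    Missing continuous covariate entries are imputed by the column mean.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, spec.n_features
    labels = rng.choice(len(spec.class_priors), size=n, p=spec.class_priors)
    x = rng.standard_normal((n, p))
    for idxs, rho in spec.corr_blocks:
        idxs = list(idxs)
        x[:, idxs] = _equicorrelated(rng, n, len(idxs), rho)
    for i, shifts in spec.informative:
        x[:, i] = x[:, i] + np.asarray(shifts)[labels]

    cov_df = None
    if spec.clinical_covariates:
        cols = {}
        for name, dist in spec.clinical_covariates.items():
            vals, continuous = _draw_covariate(rng, dist, n)
            if continuous and spec.missing_rate > 0:
                miss = rng.random(n) < spec.missing_rate
                vals = vals.copy()
                vals[miss] = np.nan
                vals = np.where(np.isnan(vals), np.nanmean(vals), vals)
            cols[name] = vals
        cov_df = pd.DataFrame(cols)

    per_config = None
    config_names = None
    if spec.n_configs > 1:
        per_config = np.repeat(x[None, :, :], spec.n_configs, axis=0).copy()
        unstable = sorted(set(spec.unstable_set))
        stable = [j for j in range(p) if j not in set(unstable)]
        for c in range(1, spec.n_configs):
            if unstable:
                factors = 1.0 + rng.normal(0.0, spec.unstable_sd, size=(n, len(unstable)))
                per_config[c][:, unstable] *= factors
            if stable and spec.stable_jitter_sd > 0:
                jitter = 1.0 + rng.normal(0.0, spec.stable_jitter_sd, size=(n, len(stable)))
                per_config[c][:, stable] *= jitter
        config_names = ["original"] + [f"config_{c:02d}" for c in range(1, spec.n_configs)]

    names = [f"f{i:03d}" for i in range(p)]
    return FeatureTable(
        features=pd.DataFrame(x, columns=names),
        labels=pd.Series(labels, name="label"),
        covariates=cov_df,
        per_config=per_config,
        config_names=config_names,
    )
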