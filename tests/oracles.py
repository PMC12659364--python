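"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity directly from its definition
with explicit loops, sharing no code path with the package
implementation it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------

def first_order_oracle(values: np.ndarray) -> dict[str, float]:
    v = [float(x) for x in np.asarray(values).ravel()]
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    sd = math.sqrt(var)
    skew = sum((x - mean) ** 3 for x in v) / n / sd**3 if sd > 0 else 0.0
    kurt = sum((x - mean) ** 4 for x in v) / n / sd**4 if sd > 0 else 0.0
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Minimum": min(v),
        "Maximum": max(v),
        "Range": max(v) - min(v),
        "Energy": sum(x * x for x in v),
        "RootMeanSquared": math.sqrt(sum(x * x for x in v) / n),
        "MeanAbsoluteDeviation": sum(abs(x - mean) for x in v) / n,
    }


def entropy_uniformity_oracle(levels: np.ndarray) -> tuple[float, float]:
    lv = [int(x) for x in np.asarray(levels).ravel()]
    n = len(lv)
    counts: dict[int, int] = {}
    for x in lv:
        counts[x] = counts.get(x, 0) + 1
    ent = -sum((c / n) * math.log2(c / n) for c in counts.values())
    uni = sum((c / n) ** 2 for c in counts.values())
    return ent, uni


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _directions_13() -> list[tuple[int, int, int]]:
    dirs: list[tuple[int, int, int]] = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0) or (-dx, -dy, -dz) in dirs:
                    continue
                dirs.append(d)
    return dirs


def glcm_oracle(levels: np.ndarray, roi: np.ndarray, ng: int) -> dict[str, float]:
    nx, ny, nz = levels.shape
    feats = {k: [] for k in ("Contrast", "Correlation", "InverseVariance", "Idm", "JointEntropy")}
    for d in _directions_13():
        mat = [[0.0] * ng for _ in range(ng)]
        total = 0
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not roi[x, y, z]:
                        continue
                    xx, yy, zz = x + d[0], y + d[1], z + d[2]
                    if not (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz):
                        continue
                    if not roi[xx, yy, zz]:
                        continue
                    i, j = levels[x, y, z], levels[xx, yy, zz]
                    mat[i - 1][j - 1] += 1
                    mat[j - 1][i - 1] += 1  # symmetric
                    total += 2
        if total == 0:
            continue
        p = [[mat[i][j] / total for j in range(ng)] for i in range(ng)]
        contrast = sum(p[i][j] * (i - j) ** 2 for i in range(ng) for j in range(ng))
        invvar = sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        )
        idm = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
        je = -sum(
            p[i][j] * math.log2(p[i][j]) for i in range(ng) for j in range(ng) if p[i][j] > 0
        )
        px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
        mu = sum((i + 1) * px[i] for i in range(ng))
        var = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
        if var > 0:
            corr = sum(
                (i + 1 - mu) * (j + 1 - mu) * p[i][j] for i in range(ng) for j in range(ng)
            ) / var
        else:
            corr = 1.0
        feats["Contrast"].append(contrast)
        feats["Correlation"].append(corr)
        feats["InverseVariance"].append(invvar)
        feats["Idm"].append(idm)
        feats["JointEntropy"].append(je)
    if not feats["Contrast"]:
        return {k: 0.0 for k in feats}
    return {k: sum(v) / len(v) for k, v in feats.items()}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_oracle(levels: np.ndarray, roi: np.ndarray, ng: int) -> dict[str, float]:
    eps = 1e-12
    nx, ny, nz = levels.shape
    n_i = [0.0] * (ng + 1)
    s_i = [0.0] * (ng + 1)
    n_valid = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not roi[x, y, z]:
                    continue
                nbrs = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if dx == dy == dz == 0:
                                continue
                            xx, yy, zz = x + dx, y + dy, z + dz
                            if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz and roi[xx, yy, zz]:
                                nbrs.append(int(levels[xx, yy, zz]))
                if not nbrs:
                    continue
                n_valid += 1
                i = int(levels[x, y, z])
                n_i[i] += 1
                s_i[i] += abs(i - sum(nbrs) / len(nbrs))
    p_i = [c / n_valid for c in n_i]
    present = [i for i in range(1, ng + 1) if p_i[i] > 0]
    sum_ps = sum(p_i[i] * s_i[i] for i in present)
    sum_s = sum(s_i[i] for i in present)
    ngp = len(present)
    coarseness = min(1.0 / max(sum_ps, eps), 1.0 / eps)
    if ngp > 1:
        contrast = (
            sum(p_i[i] * p_i[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
            * (sum_s / n_valid)
        )
        denom = sum(abs(i * p_i[i] - j * p_i[j]) for i in present for j in present)
        busyness = sum_ps / denom if denom > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j]) / (p_i[i] + p_i[j])
                for i in present
                for j in present
            )
            / n_valid
        )
        strength = sum(
            (p_i[i] + p_i[j]) * (i - j) ** 2 for i in present for j in present
        ) / (eps + sum_s)
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
# Agatston
# ---------------------------------------------------------------------------

def agatston_oracle(
    hu: np.ndarray, region: np.ndarray, spacing: tuple[float, float, float]
) -> float:
    sx, sy, sz = spacing
    pixel_area = sx * sy
    total = 0.0
    nx, ny, nzz = hu.shape
    for k in range(nzz):
        cand = [
            (x, y)
            for x in range(nx)
            for y in range(ny)
            if region[x, y, k] and hu[x, y, k] >= 130.0
        ]
        cand_set = set(cand)
        seen: set[tuple[int, int]] = set()
        for start in cand:
            if start in seen:
                continue
            lesion = []
            queue = deque([start])
            seen.add(start)
            while queue:
                cx, cy = queue.popleft()
                lesion.append((cx, cy))
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        nb = (cx + dx, cy + dy)
                        if nb in cand_set and nb not in seen:
                            seen.add(nb)
                            queue.append(nb)
            area = len(lesion) * pixel_area
            if area < 1.0 - 1e-12:
                continue
            peak = max(hu[x, y, k] for x, y in lesion)
            if peak < 200:
                w = 1
            elif peak < 300:
                w = 2
            elif peak < 400:
                w = 3
            else:
                w = 4
            total += area * w
    return total * sz / 3.0


# ---------------------------------------------------------------------------
# ring ROI
# ---------------------------------------------------------------------------

def ring_oracle(lumen: np.ndarray, width: int) -> np.ndarray:
    """Ring membership by brute-force minimum distance to any lumen voxel."""
    lum = np.argwhere(lumen)
    ring = np.zeros_like(lumen, dtype=bool)
    if len(lum) == 0:
        return ring
    nx, ny, nz = lumen.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if lumen[x, y, z]:
                    continue
                d2min = min(
                    (x - a) ** 2 + (y - b) ** 2 + (z - c) ** 2 for a, b, c in lum
                )
                if d2min <= width * width:
                    ring[x, y, z] = True
    return ring


def ring_offset_count(width: int) -> int:
    """Voxel count of the ring around a single voxel, by offset enumeration."""
    count = 0
    for dx in range(-width, width + 1):
        for dy in range(-width, width + 1):
            for dz in range(-width, width + 1):
                n2 = dx * dx + dy * dy + dz * dz
                if 0 < n2 <= width * width:
                    count += 1
    return count


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def _midranks(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = _midranks(np.asarray(x, float)), _midranks(np.asarray(y, float))
    return float(np.corrcoef(rx, ry)[0, 1])
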