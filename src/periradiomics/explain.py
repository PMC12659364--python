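"""Exact Shapley attribution for fitted classifiers on small feature
sets, with a permutation-sampling fallback.

The explanation model is additive: g(z') = phi_0 + sum_j phi_j z'_j with
all presence indicators z'_j = 1 for tabular input, so phi_0 + sum phi_j
equals the model output at the explained instance (efficiency).  The
value function is interventional: v(S) is the mean model output over the
background set with the explained instance's values imposed on the
features in S; phi_0 = v(empty set).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["Explanation", "exact_shapley", "sampled_shapley", "summarize"]

MAX_EXACT_FEATURES = 12


@dataclass
class Explanation:
    """Shapley attribution of one model output.

    ``phi0`` is the base value (mean output over the background),
    ``phi[j]`` the attribution of feature j, ``fx`` the output at the
    explained instance; presence indicators are all 1 for tabular data.
    """

    phi0: float
    phi: np.ndarray
    fx: float
    feature_names: list[str] | None = None

    @property
    def m(self) -> int:
        return len(self.phi)

    @property
    def z_prime(self) -> np.ndarray:
        return np.ones(self.m, dtype=int)

    def efficiency_residual(self) -> float:
        return float(abs(self.phi0 + self.phi.sum() - self.fx))


def _value_function_batch(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    subsets: np.ndarray,
) -> np.ndarray:
    """v(S) for every subset row (boolean matrix n_subsets x M), each the
    mean prediction over the background with x imposed on S."""
    n_sub, m = subsets.shape
    b = len(background)
    tiled = np.repeat(background[None, :, :], n_sub, axis=0)  # (n_sub, b, m)
    impose = np.broadcast_to(subsets[:, None, :], tiled.shape)
    tiled[impose] = np.broadcast_to(x, tiled.shape)[impose]
    preds = np.asarray(predict_fn(tiled.reshape(n_sub * b, m)), dtype=np.float64)
    if preds.shape != (n_sub * b,):
        raise ValueError("predict_fn must return one scalar per row")
    return preds.reshape(n_sub, b).mean(axis=1)


def exact_shapley(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    feature_names: list[str] | None = None,
) -> Explanation:
    """Exact Shapley values by full subset enumeration (M <= 12).

    phi_j = sum over S not containing j of |S|!(M-|S|-1)!/M! *
    (v(S u {j}) - v(S)).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    background = np.asarray(background, dtype=np.float64)
    if background.ndim != 2 or len(background) == 0:
        raise ValueError("background must be a nonempty 2-D array")
    m = x.size
    if background.shape[1] != m:
        raise ValueError("background width does not match the instance")
    if m > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration limited to M <= {MAX_EXACT_FEATURES} features "
            f"(got {m}); use sampled_shapley"
        )

    n_sub = 1 << m
    masks = np.arange(n_sub)
    subsets = ((masks[:, None] >> np.arange(m)) & 1).astype(bool)
    v = _value_function_batch(predict_fn, x, background, subsets)

    sizes = subsets.sum(axis=1)
    weights = np.array(
        [factorial(s) * factorial(m - s - 1) / factorial(m) for s in range(m)]
    )
    phi = np.zeros(m)
    for j in range(m):
        without_j = ~subsets[:, j]
        s_masks = masks[without_j]
        phi[j] = float(
            (weights[sizes[without_j]] * (v[s_masks | (1 << j)] - v[s_masks])).sum()
        )
    return Explanation(
        phi0=float(v[0]), phi=phi, fx=float(v[n_sub - 1]), feature_names=feature_names
    )


def sampled_shapley(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> Explanation:
    """Permutation-sampling Shapley estimator.

    Each sampled permutation adds features one at a time; the marginal
    change in the interventional value function is credited to the added
    feature.  Unbiased; converges to the exact values as n_perm grows.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=np.float64).ravel()
    background = np.asarray(background, dtype=np.float64)
    if background.ndim != 2 or len(background) == 0:
        raise ValueError("background must be a nonempty 2-D array")
    m = x.size
    rng = np.random.default_rng(seed)

    # chain subsets for all permutations, deduplicated via the value cache
    phi = np.zeros(m)
    cache: dict[int, float] = {}

    def value(mask_bits: int, subset_row: np.ndarray) -> float:
        if mask_bits not in cache:
            cache[mask_bits] = float(
                _value_function_batch(predict_fn, x, background, subset_row[None, :])[0]
            )
        return cache[mask_bits]

    empty = np.zeros(m, dtype=bool)
    v_prev_start = value(0, empty)
    for _ in range(n_perm):
        perm = rng.permutation(m)
        subset = empty.copy()
        bits = 0
        v_prev = v_prev_start
        for j in perm:
            subset[j] = True
            bits |= 1 << int(j)
            v_now = value(bits, subset)
            phi[j] += v_now - v_prev
            v_prev = v_now
    phi /= n_perm
    full = np.ones(m, dtype=bool)
    return Explanation(
        phi0=v_prev_start,
        phi=phi,
        fx=value((1 << m) - 1, full),
        feature_names=feature_names,
    )


def summarize(explanations: list[Explanation]) -> pd.DataFrame:
    """Cohort-level importance: rank features by mean |phi|; per-subject
    signed values are returned for beeswarm-style export."""
    if not explanations:
        raise ValueError("need at least one explanation")
    m = explanations[0].m
    if any(e.m != m for e in explanations):
        raise ValueError("explanations have inconsistent feature counts")
    names = explanations[0].feature_names or [f"x{j}" for j in range(m)]
    phi = np.vstack([e.phi for e in explanations])
    mean_abs = np.abs(phi).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    ranking = pd.DataFrame(
        {
            "feature": [names[j] for j in order],
            "mean_abs_phi": mean_abs[order],
            "rank": np.arange(1, m + 1),
        }
    )
    ranking.attrs["phi_matrix"] = pd.DataFrame(phi, columns=names)
    return ranking
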