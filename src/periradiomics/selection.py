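"""Data-driven feature reduction and the five pipeline variants.

Reduction is a greedy Pearson correlation prune (|r| > 0.9 keeps only
one of a correlated pair) followed by one-vs-rest L1-penalized logistic
regression with the penalty chosen by cross-validated deviance; the
selected support is the union of nonzero coefficients across classes.

The five pipeline variants compared in the analysis:

1. ``all``                          - every feature, no selection
2. ``stable_only``                  - stability-screen filter only
3. ``all_datadriven``               - Pearson + LASSO on all features
4. ``stable_datadriven``            - stability filter, then Pearson + LASSO
5. ``stable_datadriven_clinical``   - variant 4 plus clinical covariates
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

log = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "SelectionResult",
    "pearson_prune",
    "lasso_cv_select",
    "build_variant",
]

VARIANTS = {
    1: "all",
    2: "stable_only",
    3: "all_datadriven",
    4: "stable_datadriven",
    5: "stable_datadriven_clinical",
}


@dataclass
class SelectionResult:
    variant: str
    kept_names: list[str] = field(default_factory=list)
    support_names: list[str] = field(default_factory=list)
    lambda_per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "kept_names": self.kept_names,
            "support_names": self.support_names,
            "lambda_per_class": {str(k): v for k, v in self.lambda_per_class.items()},
        }


def pearson_prune(
    table: pd.DataFrame, threshold: float = 0.9, order: str = "variance"
) -> list[str]:
    """Greedy correlation prune: walk features in descending-variance
    order, keep a feature iff |r| <= threshold against every feature
    already kept.  Zero-variance features are dropped first.

    Deterministic; ties in the ordering break by column position.
    ``order`` may be "variance" (default) or a list-like of ranks
    (ascending = keep first), allowing a stability-rank ordering.
    """
    if table.shape[1] == 0 or table.shape[0] < 2:
        raise ValueError("Pearson pruning needs a nonempty table with >= 2 subjects")
    variances = table.var(axis=0, ddof=1)
    nonzero = variances[variances > 0].index.tolist()
    dropped = [c for c in table.columns if c not in set(nonzero)]
    if dropped:
        log.info("Pearson prune: dropped %d zero-variance features", len(dropped))
    if not nonzero:
        return []

    if isinstance(order, str):
        if order != "variance":
            raise ValueError(f"unknown ordering {order!r}")
        ranked = sorted(nonzero, key=lambda c: (-variances[c], table.columns.get_loc(c)))
    else:
        rank_map = dict(zip(table.columns, order))
        ranked = sorted(nonzero, key=lambda c: (rank_map[c], table.columns.get_loc(c)))

    sub = table[ranked].to_numpy(dtype=np.float64)
    sub = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    corr = np.abs(sub.T @ sub) / (len(table) - 1)

    kept_idx: list[int] = []
    for j in range(len(ranked)):
        if all(corr[j, k] <= threshold + 1e-12 for k in kept_idx):
            kept_idx.append(j)
    kept = {ranked[j] for j in kept_idx}
    return [c for c in table.columns if c in kept]


def _lambda_grid(x: np.ndarray, labels: np.ndarray, n_points: int) -> np.ndarray:
    """Data-scaled log grid: from the smallest penalty that zeroes every
    coefficient in the one-vs-rest problems down by three decades."""
    n = len(labels)
    lam_max = 0.0
    for cls in np.unique(labels):
        y = (labels == cls).astype(np.float64)
        lam_max = max(lam_max, float(np.abs(x.T @ (y - y.mean())).max()) / n)
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - 3.0, n_points)


def lasso_cv_select(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 50,
    seed: int = 0,
) -> tuple[list[str], dict]:
    """One-vs-rest L1 logistic regression; per class, the penalty
    minimizing the mean cross-validated deviance is chosen and the
    support is the union of nonzero coefficients across classes.

    Returns ``(support_names, lambda_per_class)``.
    """
    y_all = np.asarray(labels)
    classes = np.unique(y_all)
    if len(classes) < 2:
        raise ValueError("LASSO selection needs at least two classes")
    scaler = StandardScaler()
    x = scaler.fit_transform(table.to_numpy(dtype=np.float64))
    n = len(y_all)
    grid = lambda_grid if lambda_grid is not None else _lambda_grid(x, y_all, n_lambda)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y_all))

    support: set[str] = set()
    lam_chosen: dict = {}
    # a binary problem needs a single one-vs-rest fit; its complement is identical
    ovr_classes = classes[1:] if len(classes) == 2 else classes
    for cls in ovr_classes:
        y = (y_all == cls).astype(int)
        if y.sum() == 0 or y.sum() == n:
            raise ValueError(f"class {cls} is degenerate in the one-vs-rest problem")
        deviance = np.zeros(len(grid))
        for tr, te in splits:
            x_tr = x[tr]
            mu = x_tr.mean(axis=0)
            sd = x_tr.std(axis=0)
            sd[sd == 0] = 1.0
            x_trs, x_tes = (x_tr - mu) / sd, (x[te] - mu) / sd
            for g, lam in enumerate(grid):
                clf = LogisticRegression(
                    l1_ratio=1.0, C=1.0 / (lam * len(tr)), solver="liblinear", max_iter=500
                )
                clf.fit(x_trs, y[tr])
                prob = clf.predict_proba(x_tes)[:, 1]
                deviance[g] += log_loss(y[te], prob, labels=[0, 1]) * len(te)
        best = int(np.argmin(deviance / n))
        lam = float(grid[best])
        lam_chosen[cls] = lam
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (lam * n), solver="liblinear", max_iter=500
        )
        clf.fit(x, y)
        support.update(np.asarray(table.columns)[np.abs(clf.coef_[0]) > 1e-10])

    return [c for c in table.columns if c in support], lam_chosen


def build_variant(
    variant_id: int | str,
    stability_report=None,
    clinical_table: pd.DataFrame | None = None,
) -> list[dict]:
    """Ordered stage list for one pipeline variant.

    Stages are descriptors ``{"stage": ..., **params}`` consumed by the
    pipeline runner; variants using the stability filter require a
    stability report, and the clinical variant a covariate table.
    """
    if isinstance(variant_id, str):
        inverse = {v: k for k, v in VARIANTS.items()}
        if variant_id not in inverse:
            raise ValueError(f"unknown variant {variant_id!r}")
        variant_id = inverse[variant_id]
    if variant_id not in VARIANTS:
        raise ValueError(f"unknown variant {variant_id!r}; expected 1..5")
    name = VARIANTS[variant_id]

    stages: list[dict] = []
    if variant_id in (2, 4, 5):
        if stability_report is None:
            raise ValueError(f"variant {variant_id} needs a stability report")
        stages.append({"stage": "stable_filter", "report": stability_report})
    if variant_id in (3, 4, 5):
        stages.append({"stage": "pearson_prune", "threshold": 0.9})
        stages.append({"stage": "lasso_cv"})
    if variant_id == 5:
        if clinical_table is None:
            raise ValueError("variant 5 needs a clinical covariate table")
        # clinical covariates join after selection and bypass the penalty
        stages.append({"stage": "append_clinical", "table": clinical_table})
    return [{"stage": "variant", "name": name}] + stages
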