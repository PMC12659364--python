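"""Six-algorithm classification harness with stratified cross-validation
and multi-class ROC metrics.

Evaluation protocol: stratified outer 5-fold split; within each outer
training portion a stratified 20% *inner test* split is held out, the
model is fit on the remaining 80%, and evaluated on (a) that inner test
set and (b) the outer held-out fold (the *validation* set).  Reported
"train"/"test" accuracies mirror this: train = fit-set accuracy, test =
pooled inner-test accuracy.  Accuracy confidence intervals are exact
Clopper-Pearson 95% bounds on the pooled counts; AUCs are one-vs-rest
trapezoidal, with micro (pooled binary indicators) and macro (unweighted
class mean) averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .synthetic import SEGMENTS

__all__ = [
    "ALGORITHMS",
    "CVSpec",
    "ModelReport",
    "make_model",
    "make_folds",
    "train_eval",
    "segment_models",
]

ALGORITHMS = ("svm", "knn", "mlp", "naive_bayes", "gradient_boosting", "light_gbm_style")


def make_model(algorithm: str, seed: int = 0):
    """Instantiate one registry entry.  Scale-sensitive learners are
    wrapped with standardization; tree ensembles are not."""
    if algorithm == "svm":
        return make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=10.0, gamma="scale", probability=True,
                                  random_state=seed)
        )
    if algorithm == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    if algorithm == "mlp":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(64,), max_iter=600, random_state=seed),
        )
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=150, max_depth=3, random_state=seed)
    if algorithm == "light_gbm_style":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=150,
            num_leaves=15,
            min_child_samples=5,
            random_state=seed,
            verbose=-1,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; registry: {ALGORITHMS}")


@dataclass
class CVSpec:
    """Cross-validation layout: outer folds and the inner test fraction
    carved from each outer training portion."""

    folds: int = 5
    inner_test_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 outer folds")
        if not (0.0 < self.inner_test_fraction < 1.0):
            raise ValueError("inner test fraction must lie in (0, 1)")


@dataclass
class FoldAssignment:
    fit_idx: np.ndarray
    inner_test_idx: np.ndarray
    val_idx: np.ndarray


@dataclass
class ModelReport:
    algorithm: str
    train_accuracy: float
    train_ci: tuple[float, float]
    test_accuracy: float
    test_ci: tuple[float, float]
    val_accuracy: float
    per_class_auc: dict
    micro_auc: float
    macro_auc: float
    confusion: pd.DataFrame
    n_test: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "train_accuracy": self.train_accuracy,
            "train_ci": list(self.train_ci),
            "test_accuracy": self.test_accuracy,
            "test_ci": list(self.test_ci),
            "val_accuracy": self.val_accuracy,
            "per_class_auc": {str(k): v for k, v in self.per_class_auc.items()},
            "micro_auc": self.micro_auc,
            "macro_auc": self.macro_auc,
            "n_test": self.n_test,
            "confusion": self.confusion.to_dict(),
        }


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval."""
    if n == 0:
        return (0.0, 1.0)
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return (lo, hi)


def make_folds(n: int, labels: np.ndarray, spec: CVSpec) -> list[FoldAssignment]:
    """Stratified outer folds with a stratified inner test split inside
    each outer training portion; deterministic under ``spec.seed``."""
    y = np.asarray(labels)
    if len(y) != n:
        raise ValueError("labels length does not match n")
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < spec.folds]
    if len(too_small):
        raise ValueError(
            f"classes with fewer members than folds ({spec.folds}): {list(too_small)}"
        )
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    folds = []
    for train_idx, val_idx in skf.split(np.zeros(n), y):
        fit_idx, inner_idx = train_test_split(
            train_idx,
            test_size=spec.inner_test_fraction,
            stratify=y[train_idx],
            random_state=spec.seed,
        )
        assert not set(inner_idx) & set(fit_idx)
        assert not set(val_idx) & set(train_idx)
        folds.append(FoldAssignment(np.sort(fit_idx), np.sort(inner_idx), np.sort(val_idx)))
    return folds


def _check_features(table: pd.DataFrame) -> np.ndarray:
    x = table.to_numpy(dtype=np.float64)
    bad = ~np.isfinite(x)
    if bad.any():
        cols = table.columns[bad.any(axis=0)].tolist()
        raise ValueError(f"non-finite feature values in columns {cols}")
    return x


def train_eval(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    algorithm: str,
    spec: CVSpec | None = None,
) -> ModelReport:
    """Fit/evaluate one algorithm under the cross-validation protocol."""
    spec = spec or CVSpec()
    x = _check_features(table)
    y = np.asarray(labels)
    classes = np.unique(y)
    folds = make_folds(len(y), y, spec)

    train_correct = train_total = 0
    test_correct = 0
    val_correct = val_total = 0
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    pooled_score: list[np.ndarray] = []

    for fold in folds:
        model = make_model(algorithm, seed=spec.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x[fold.fit_idx], y[fold.fit_idx])
            train_pred = model.predict(x[fold.fit_idx])
            test_pred = model.predict(x[fold.inner_test_idx])
            val_pred = model.predict(x[fold.val_idx])
            score = model.predict_proba(x[fold.inner_test_idx])
        train_correct += int((train_pred == y[fold.fit_idx]).sum())
        train_total += len(fold.fit_idx)
        test_correct += int((test_pred == y[fold.inner_test_idx]).sum())
        val_correct += int((val_pred == y[fold.val_idx]).sum())
        val_total += len(fold.val_idx)
        pooled_true.append(y[fold.inner_test_idx])
        pooled_pred.append(test_pred)
        # align score columns to the global class list
        aligned = np.zeros((len(fold.inner_test_idx), len(classes)))
        model_classes = list(model.classes_) if hasattr(model, "classes_") else list(
            model.named_steps[list(model.named_steps)[-1]].classes_
        )
        for col, cls in enumerate(model_classes):
            aligned[:, list(classes).index(cls)] = score[:, col]
        pooled_score.append(aligned)

    y_true = np.concatenate(pooled_true)
    y_pred = np.concatenate(pooled_pred)
    scores = np.vstack(pooled_score)
    n_test = len(y_true)

    onehot = (y_true[:, None] == classes[None, :]).astype(int)
    per_class_auc: dict = {}
    aucs = []
    for k, cls in enumerate(classes):
        if onehot[:, k].min() == onehot[:, k].max():
            per_class_auc[cls] = float("nan")
            continue
        auc = float(roc_auc_score(onehot[:, k], scores[:, k]))
        per_class_auc[cls] = auc
        aucs.append(auc)
    micro = float(roc_auc_score(onehot.ravel(), scores.ravel()))
    macro = float(np.mean(aucs)) if aucs else float("nan")

    conf = pd.DataFrame(
        confusion_matrix(y_true, y_pred, labels=classes), index=classes, columns=classes
    )
    return ModelReport(
        algorithm=algorithm,
        train_accuracy=train_correct / train_total,
        train_ci=clopper_pearson(train_correct, train_total),
        test_accuracy=test_correct / n_test,
        test_ci=clopper_pearson(test_correct, n_test),
        val_accuracy=val_correct / val_total,
        per_class_auc=per_class_auc,
        micro_auc=micro,
        macro_auc=macro,
        confusion=conf,
        n_test=n_test,
    )


def segment_models(
    segment_tables: dict[str, tuple[pd.DataFrame, np.ndarray]],
    spec: CVSpec | None = None,
    algorithms: tuple[str, ...] = ALGORITHMS,
) -> dict[str, dict[str, ModelReport]]:
    """Independent models per coronary segment plus an all-segments
    pooled run; returns {segment or 'pooled': {algorithm: report}}."""
    for seg in segment_tables:
        if seg not in SEGMENTS:
            raise ValueError(f"unknown segment id {seg!r}; expected one of {SEGMENTS}")
    out: dict[str, dict[str, ModelReport]] = {}
    for seg, (table, labels) in segment_tables.items():
        out[seg] = {alg: train_eval(table, labels, alg, spec) for alg in algorithms}
    pooled_x = pd.concat([t for t, _ in segment_tables.values()], ignore_index=True)
    pooled_y = np.concatenate([np.asarray(l) for _, l in segment_tables.values()])
    out["pooled"] = {alg: train_eval(pooled_x, pooled_y, alg, spec) for alg in algorithms}
    return out
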