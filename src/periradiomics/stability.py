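"""Feature-stability screening across the imaging-configuration grid.

The stability index Δr of a feature is the mean, over subjects, of its
coefficient of variation across all imaging configurations:
``CV = sd_configs / (|mean_configs| + eps)`` with ``eps = 1e-12``
guarding zero means.  A feature is *stable* if Δr < 0.25 and *highly
stable* if Δr < 0.1.  Per-configuration deviation is the mean, over
subjects, of the relative deviation from the original (no-resampling)
setting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StabilityReport",
    "overall_stability",
    "per_config_deviation",
    "stability_screen",
    "spearman_assoc",
]

_EPS = 1e-12

STABLE_THRESHOLD = 0.25
HIGHLY_STABLE_THRESHOLD = 0.10


@dataclass
class StabilityReport:
    """Per-feature Δr values, per-config deviations, and flags.

    Flags are a pure function of the stored Δr values and thresholds, so
    they can be recomputed after (de)serialization.
    """

    feature_names: list[str]
    delta_r: np.ndarray  # (n_features,)
    per_config: pd.DataFrame  # configs x features mean relative deviation
    n_subjects: int
    stable_threshold: float = STABLE_THRESHOLD
    highly_stable_threshold: float = HIGHLY_STABLE_THRESHOLD
    degenerate: list[str] = field(default_factory=list)

    @property
    def stable(self) -> np.ndarray:
        return self.delta_r < self.stable_threshold

    @property
    def highly_stable(self) -> np.ndarray:
        return self.delta_r < self.highly_stable_threshold

    def stable_names(self) -> list[str]:
        return [n for n, s in zip(self.feature_names, self.stable) if s]

    def per_config_stable_fraction(self, threshold: float | None = None) -> pd.Series:
        """Share of features whose deviation from the original setting is
        below the threshold, per configuration."""
        thr = self.stable_threshold if threshold is None else threshold
        return (self.per_config < thr).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "delta_r": self.delta_r,
                "stable": self.stable,
                "highly_stable": self.highly_stable,
                "degenerate": [n in set(self.degenerate) for n in self.feature_names],
            }
        )

    def save(self, csv_path: str, json_path: str | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(
                    {
                        "n_subjects": self.n_subjects,
                        "n_features": len(self.feature_names),
                        "n_stable": int(self.stable.sum()),
                        "n_highly_stable": int(self.highly_stable.sum()),
                        "stable_threshold": self.stable_threshold,
                        "highly_stable_threshold": self.highly_stable_threshold,
                        "delta_r_definition": "mean over subjects of across-config CV, eps=1e-12",
                        "per_config_reference": "original",
                        "degenerate": self.degenerate,
                    },
                    fh,
                    indent=2,
                )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        per_config: pd.DataFrame,
        n_subjects: int,
        stable_threshold: float = STABLE_THRESHOLD,
        highly_stable_threshold: float = HIGHLY_STABLE_THRESHOLD,
    ) -> "StabilityReport":
        return cls(
            feature_names=list(frame["feature"]),
            delta_r=frame["delta_r"].to_numpy(),
            per_config=per_config,
            n_subjects=n_subjects,
            stable_threshold=stable_threshold,
            highly_stable_threshold=highly_stable_threshold,
            degenerate=list(frame.loc[frame["degenerate"], "feature"]) if "degenerate" in frame else [],
        )


def _as_panel(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 2:  # subjects x configs, single feature
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("expected values shaped (subjects, configs[, features])")
    if arr.shape[1] < 2:
        raise ValueError("stability needs at least 2 configurations")
    if arr.shape[0] < 1:
        raise ValueError("stability needs at least 1 subject")
    if not np.all(np.isfinite(arr)):
        raise ValueError("stability input contains non-finite values")
    return arr


def overall_stability(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Δr per feature from a (subjects, configs[, features]) array.

    Returns ``(delta_r, stable, highly_stable)``; scalar-feature inputs
    return length-1 arrays.  All-zero features get Δr = 0 through the
    eps guard (degenerate, but flagged stable by construction).
    """
    arr = _as_panel(values)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    cv = sd / (np.abs(mean) + _EPS)
    delta_r = cv.mean(axis=0)
    return delta_r, delta_r < STABLE_THRESHOLD, delta_r < HIGHLY_STABLE_THRESHOLD


def per_config_deviation(values: np.ndarray, baseline_index: int = 0) -> np.ndarray:
    """Mean over subjects of |v_c - v_0| / (|v_0| + eps) per config and
    feature; row ``baseline_index`` is the original setting."""
    arr = _as_panel(values)
    if not (0 <= baseline_index < arr.shape[1]):
        raise ValueError("baseline configuration missing from the panel")
    base = arr[:, baseline_index, :]
    dev = np.abs(arr - base[:, None, :]) / (np.abs(base[:, None, :]) + _EPS)
    return dev.mean(axis=0)


def stability_screen(
    panel: np.ndarray,
    feature_names: list[str],
    config_names: list[str] | None = None,
    baseline_index: int = 0,
) -> StabilityReport:
    """Full screen over a (configs, subjects, features) panel.

    Note the panel axis order matches the cohort generator's
    ``per_config`` layout (configs first); it is transposed internally to
    the per-subject layout the Δr formula is written in.
    """
    arr = np.asarray(panel, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("panel must be shaped (configs, subjects, features)")
    subj_first = np.transpose(arr, (1, 0, 2))
    delta_r, _, _ = overall_stability(subj_first)
    dev = per_config_deviation(subj_first, baseline_index)
    names_cfg = config_names or [f"config_{i:02d}" for i in range(arr.shape[0])]
    degenerate = [
        n for j, n in enumerate(feature_names) if np.allclose(arr[:, :, j], 0.0)
    ]
    return StabilityReport(
        feature_names=list(feature_names),
        delta_r=delta_r,
        per_config=pd.DataFrame(dev, index=names_cfg, columns=feature_names),
        n_subjects=arr.shape[1],
        degenerate=degenerate,
    )


def spearman_assoc(feature_values: np.ndarray, scores: np.ndarray) -> float:
    """Spearman rank correlation (mid-ranks for ties) between one feature
    and a score vector; NaN when either vector is constant."""
    x = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(scores, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expected two paired 1-D vectors")
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
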