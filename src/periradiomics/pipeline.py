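"""End-to-end orchestration: phantom simulation, 21-configuration
feature extraction, stability screening, variant selection, model
training, and Shapley explanation, with all artifacts written as
CSV/JSON plus a manifest.

The default phantom study emulates the clinical analysis at desk scale:
a lesion-free subcohort is screened for feature stability across the
full perturbation grid (mirroring the disease-free stability cohort of
the clinical design), and a diseased cohort with graded stenosis and
calcific burden is classified from original-setting features filtered
through the chosen pipeline variant.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .explain import Explanation, exact_shapley, sampled_shapley, summarize
from .features import ExtractionSpec, extract_all, feature_names
from .image_ops import ImagingConfig, enumerate_configs
from .models import ALGORITHMS, CVSpec, ModelReport, make_model, segment_models, train_eval
from .selection import VARIANTS, SelectionResult, build_variant, lasso_cv_select, pearson_prune
from .stability import StabilityReport, stability_screen
from .synthetic import SEGMENTS, PhantomSpec, generate_vessel_phantom

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "make_phantom_cohort_specs", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name (and subject, if known)."""

    def __init__(self, stage: str, message: str, subject: int | None = None):
        self.stage = stage
        self.subject = subject
        where = f"stage {stage!r}" + (f", subject {subject}" if subject is not None else "")
        super().__init__(f"{where}: {message}")


# severity ranges of the three stenosis grades planted in the cohort
_SEVERITY_RANGES = ((0.0, 0.05), (0.15, 0.45), (0.55, 0.85))

# calcific burden tiers targeting the four Agatston categories:
# (number of plaques, radius mm, peak HU)
_CAC_TIERS = (
    (0, 0.0, 0.0),
    (2, 2.5, 300.0),
    (3, 3.0, 450.0),
    (6, 3.2, 900.0),
)

# burden-tier mix per stenosis grade: calcific burden rises with stenosis
# severity, as it does clinically, while keeping every Agatston category
# populated in the cohort
_TIER_MIX = (
    (0.60, 0.25, 0.10, 0.05),  # no stenosis
    (0.15, 0.45, 0.25, 0.15),  # mild
    (0.05, 0.15, 0.35, 0.45),  # significant
)


def _tier_sequence(n: int, mix: tuple[float, ...]) -> list[int]:
    """Deterministic largest-remainder apportionment of burden tiers."""
    exact = [n * p for p in mix]
    counts = [int(e) for e in exact]
    rem = sorted(range(len(mix)), key=lambda k: exact[k] - counts[k], reverse=True)
    for k in rem[: n - sum(counts)]:
        counts[k] += 1
    seq: list[int] = []
    for tier, c in enumerate(counts):
        seq.extend([tier] * c)
    return seq


@dataclass
class RunConfig:
    """One pipeline run.  All randomness flows from ``seed``; stage seeds
    are derived with fixed offsets so stages are independently
    reproducible."""

    n_per_stenosis_class: int = 40
    n_stability_subjects: int = 15
    seed: int = 0
    variant: int = 4
    algorithms: tuple[str, ...] = ALGORITHMS
    stable_threshold: float = 0.25
    highly_stable_threshold: float = 0.10
    noise_sd_hu: float = 15.0
    extraction: ExtractionSpec = field(default_factory=ExtractionSpec)
    cv: CVSpec | None = None
    explain_subjects: int = 12
    explain_background: int = 24
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.highly_stable_threshold < self.stable_threshold):
            raise ValueError("thresholds must satisfy 0 < highly_stable < stable")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {sorted(VARIANTS)}")
        if self.cv is None:
            self.cv = CVSpec(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        extraction = ExtractionSpec(**raw.pop("extraction", {})) if "extraction" in raw else ExtractionSpec()
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(extraction=extraction, **raw)

    def config_hash(self) -> str:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k not in ("extraction", "cv", "output_dir")
        }
        payload["extraction"] = self.extraction.to_dict()
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# phantom cohort design
# ---------------------------------------------------------------------------

def _plaques_for_tier(
    rng: np.random.Generator, tier: int, center_xy: np.ndarray, lumen_radius: float,
    z_extent: float,
) -> list:
    count, radius, peak = _CAC_TIERS[tier]
    plaques = []
    if count == 0:
        return plaques
    z_slots = np.linspace(0.25 * z_extent, 0.75 * z_extent, count)
    for z in z_slots:
        angle = rng.uniform(0, 2 * np.pi)
        r = lumen_radius + 1.0
        cx = center_xy[0] + r * np.cos(angle)
        cy = center_xy[1] + r * np.sin(angle)
        plaques.append(
            (
                (float(cx), float(cy), float(z)),
                float(radius * rng.uniform(0.9, 1.1)),
                float(peak * rng.uniform(0.92, 1.08)),
            )
        )
    return plaques


def make_phantom_cohort_specs(
    n_per_class: int,
    seed: int,
    noise_sd_hu: float = 15.0,
    lesion_free: bool = False,
    n_subjects: int | None = None,
) -> list[PhantomSpec]:
    """Design the phantom cohort.

    Diseased cohort: 3 stenosis grades x n_per_class subjects, calcific
    burden tier cycled 0..3 within each grade block, segment label cycled
    over the five major segments.  ``lesion_free=True`` instead yields
    ``n_subjects`` stenosis- and plaque-free phantoms (the stability
    subcohort).
    """
    base = PhantomSpec()
    nx, ny, nz = base.grid_shape
    sx, sy, sz = base.spacing_mm
    z_extent = (nz - 1) * sz
    total = n_subjects if lesion_free else 3 * n_per_class
    tier_seqs = [] if lesion_free else [_tier_sequence(n_per_class, m) for m in _TIER_MIX]
    specs = []
    for i in range(total):
        rng = np.random.default_rng((seed * 100003 + i) % (2**31 - 1))
        cx = (nx - 1) * sx / 2 + rng.uniform(-0.75, 0.75)
        cy = (ny - 1) * sy / 2 + rng.uniform(-0.75, 0.75)
        centerline = [[cx, cy, 0.0], [cx, cy, z_extent]]
        stenoses = []
        plaques = []
        if not lesion_free:
            grade = i // n_per_class
            lo, hi = _SEVERITY_RANGES[grade]
            sev = float(rng.uniform(lo, hi))
            if sev > 0.02:
                stenoses = [(float(rng.uniform(0.4, 0.6)), sev, float(rng.uniform(12.0, 18.0)))]
            tier = tier_seqs[grade][i % n_per_class]
            plaques = _plaques_for_tier(
                rng, tier, np.array([cx, cy]), base.lumen_radius_mm, z_extent
            )
        specs.append(
            PhantomSpec(
                centerline=centerline,
                stenoses=stenoses,
                plaques=plaques,
                noise_sd_hu=noise_sd_hu,
                seed=int(rng.integers(0, 2**31 - 1)),
                segment_id=SEGMENTS[i % len(SEGMENTS)],
            )
        )
    return specs


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _extract_panel(
    phantoms: list, configs: list[ImagingConfig], spec: ExtractionSpec
) -> np.ndarray:
    names = feature_names(spec)
    panel = np.empty((len(configs), len(phantoms), len(names)))
    for s, (vol, mask, _truth) in enumerate(phantoms):
        for c, cfg in enumerate(configs):
            try:
                panel[c, s, :] = extract_all(vol, mask, cfg, spec).to_numpy()
            except Exception as exc:  # pragma: no cover - defensive
                raise PipelineError("extract", str(exc), subject=s) from exc
    if np.isnan(panel).any():
        raise PipelineError("extract", "a subject produced missing features")
    return panel


def _apply_variant_stages(
    features: pd.DataFrame,
    labels: np.ndarray,
    stages: list[dict],
    seed: int,
) -> tuple[pd.DataFrame, SelectionResult]:
    """Run the selection stage list on one task's feature table."""
    variant_name = stages[0]["name"]
    table = features
    result = SelectionResult(variant=variant_name, kept_names=list(table.columns))
    for stage in stages[1:]:
        kind = stage["stage"]
        if kind == "stable_filter":
            report: StabilityReport = stage["report"]
            keep = [c for c in table.columns if c in set(report.stable_names())]
            if not keep:
                raise PipelineError("select", "no stable features survive the filter")
            table = table[keep]
            result.kept_names = keep
        elif kind == "pearson_prune":
            kept = pearson_prune(table, threshold=stage.get("threshold", 0.9))
            table = table[kept]
            result.kept_names = kept
        elif kind == "lasso_cv":
            support, lam = lasso_cv_select(table, labels, seed=seed)
            if support:  # an all-noise table may legitimately select nothing
                table = table[support]
            result.support_names = support
            result.lambda_per_class = lam
        elif kind == "append_clinical":
            clin = stage["table"].reset_index(drop=True)
            table = pd.concat([table.reset_index(drop=True), clin], axis=1)
        else:
            raise PipelineError("select", f"unknown stage {kind!r}")
    if not result.support_names:
        result.support_names = list(table.columns)
    return table, result


def _explain_model(
    table: pd.DataFrame,
    labels: np.ndarray,
    algorithm: str,
    cfg: RunConfig,
) -> tuple[list[Explanation], pd.DataFrame]:
    model = make_model(algorithm, seed=cfg.seed)
    x = table.to_numpy(dtype=np.float64)
    model.fit(x, labels)
    rng = np.random.default_rng(cfg.seed + 71)
    bg_idx = rng.choice(len(x), size=min(cfg.explain_background, len(x)), replace=False)
    background = x[bg_idx]
    subj_idx = rng.choice(len(x), size=min(cfg.explain_subjects, len(x)), replace=False)
    names = list(table.columns)

    explanations = []
    for i in subj_idx:
        xi = x[i]
        cls_col = int(np.where(model.classes_ == model.predict(xi[None, :])[0])[0][0])

        def predict_fn(rows: np.ndarray, _col=cls_col) -> np.ndarray:
            return model.predict_proba(rows)[:, _col]

        if x.shape[1] <= 12:
            expl = exact_shapley(predict_fn, xi, background, feature_names=names)
        else:
            expl = sampled_shapley(
                predict_fn, xi, background, n_perm=64, seed=cfg.seed + int(i),
                feature_names=names,
            )
        explanations.append(expl)
    return explanations, summarize(explanations)


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full phantom study; returns a result bundle and, when
    ``cfg.output_dir`` is set, writes every artifact with a manifest."""
    configs = enumerate_configs()

    log.info("simulate: stability subcohort (%d lesion-free phantoms)", cfg.n_stability_subjects)
    stab_specs = make_phantom_cohort_specs(
        0, seed=cfg.seed + 1, noise_sd_hu=cfg.noise_sd_hu,
        lesion_free=True, n_subjects=cfg.n_stability_subjects,
    )
    try:
        stab_phantoms = [generate_vessel_phantom(s) for s in stab_specs]
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    log.info("extract: stability panel across %d configs", len(configs))
    panel = _extract_panel(stab_phantoms, configs, cfg.extraction)
    names = feature_names(cfg.extraction)
    report = stability_screen(panel, names, [c.name for c in configs])
    report.stable_threshold = cfg.stable_threshold
    report.highly_stable_threshold = cfg.highly_stable_threshold

    log.info("simulate: modeling cohort (%d phantoms)", 3 * cfg.n_per_stenosis_class)
    specs = make_phantom_cohort_specs(
        cfg.n_per_stenosis_class, seed=cfg.seed + 2, noise_sd_hu=cfg.noise_sd_hu
    )
    try:
        phantoms = [generate_vessel_phantom(s) for s in specs]
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    truths = [t for _, _, t in phantoms]

    log.info("extract: modeling cohort at the original setting")
    original = configs[0]
    rows = []
    for s, (vol, mask, _t) in enumerate(phantoms):
        try:
            rows.append(extract_all(vol, mask, original, cfg.extraction))
        except Exception as exc:
            raise PipelineError("extract", str(exc), subject=s) from exc
    features = pd.DataFrame(rows).reset_index(drop=True)
    if features.isna().any().any():
        raise PipelineError("extract", "missing features in the modeling cohort")

    cac_labels = np.array([t.cac_class for t in truths])
    sten_labels = np.array([t.stenosis_class3 for t in truths])
    segments = np.array([t.segment_id for t in truths])

    stages = build_variant(cfg.variant, stability_report=report)

    log.info("select: variant %s for the calcification task", cfg.variant)
    cac_table, cac_sel = _apply_variant_stages(features, cac_labels, stages, cfg.seed)
    log.info("select: variant %s for the stenosis task", cfg.variant)
    sten_table, sten_sel = _apply_variant_stages(features, sten_labels, stages, cfg.seed)

    log.info("train: calcification models (%s)", ",".join(cfg.algorithms))
    cac_reports = {
        alg: train_eval(cac_table, cac_labels, alg, cfg.cv) for alg in cfg.algorithms
    }

    log.info("train: per-segment stenosis models")
    seg_tables = {
        seg: (sten_table[segments == seg].reset_index(drop=True), sten_labels[segments == seg])
        for seg in SEGMENTS
    }
    sten_reports = segment_models(seg_tables, cfg.cv, algorithms=cfg.algorithms)

    log.info("explain: Shapley attribution of the SVM calcification model")
    explanations, ranking = _explain_model(cac_table, cac_labels, "svm", cfg)

    results = {
        "config": cfg,
        "configs": configs,
        "stability": report,
        "features": features,
        "truths": truths,
        "cac_selection": cac_sel,
        "stenosis_selection": sten_sel,
        "cac_reports": cac_reports,
        "stenosis_reports": sten_reports,
        "explanations": explanations,
        "explanation_ranking": ranking,
    }
    if cfg.output_dir:
        _write_bundle(results, cfg)
    return results


# ---------------------------------------------------------------------------
# artifact writing
# ---------------------------------------------------------------------------

def _report_frame(reports: dict[str, ModelReport]) -> pd.DataFrame:
    rows = []
    for alg, r in reports.items():
        rows.append(
            {
                "algorithm": alg,
                "train_accuracy": r.train_accuracy,
                "train_ci_lo": r.train_ci[0],
                "train_ci_hi": r.train_ci[1],
                "test_accuracy": r.test_accuracy,
                "test_ci_lo": r.test_ci[0],
                "test_ci_hi": r.test_ci[1],
                "val_accuracy": r.val_accuracy,
                "micro_auc": r.micro_auc,
                "macro_auc": r.macro_auc,
            }
        )
    return pd.DataFrame(rows)


def _write_bundle(results: dict, cfg: RunConfig) -> None:
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    chash = cfg.config_hash()

    feats: pd.DataFrame = results["features"].copy()
    feats["label"] = [t.cac_class for t in results["truths"]]
    feats["stenosis_class3"] = [t.stenosis_class3 for t in results["truths"]]
    feats["segment_id"] = [t.segment_id for t in results["truths"]]
    feats["agatston_au"] = [t.agatston_au for t in results["truths"]]
    feats.to_csv(os.path.join(out, "features.csv"), index=False)

    report: StabilityReport = results["stability"]
    report.save(os.path.join(out, "stability.csv"), os.path.join(out, "stability.json"))
    with open(os.path.join(out, "stable_features.txt"), "w") as fh:
        fh.write("\n".join(report.stable_names()) + "\n")

    with open(os.path.join(out, "selection.json"), "w") as fh:
        json.dump(
            {
                "cac": results["cac_selection"].to_dict(),
                "stenosis": results["stenosis_selection"].to_dict(),
            },
            fh,
            indent=2,
        )

    _report_frame(results["cac_reports"]).to_csv(
        os.path.join(out, "cac_model_performance.csv"), index=False
    )
    pooled = results["stenosis_reports"]["pooled"]
    _report_frame(pooled).to_csv(
        os.path.join(out, "stenosis_pooled_performance.csv"), index=False
    )
    seg_rows = []
    for seg, reports in results["stenosis_reports"].items():
        frame = _report_frame(reports)
        frame.insert(0, "segment", seg)
        seg_rows.append(frame)
    pd.concat(seg_rows, ignore_index=True).to_csv(
        os.path.join(out, "stenosis_segment_performance.csv"), index=False
    )
    for alg, r in results["cac_reports"].items():
        r.confusion.to_csv(os.path.join(out, f"confusion_cac_{alg}.csv"))

    ranking: pd.DataFrame = results["explanation_ranking"]
    ranking.to_csv(os.path.join(out, "shapley_ranking.csv"), index=False)
    phi = ranking.attrs.get("phi_matrix")
    if phi is not None:
        phi.to_csv(os.path.join(out, "shapley_values.csv"), index=False)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": chash,
        "variant": VARIANTS[cfg.variant],
        "n_per_stenosis_class": cfg.n_per_stenosis_class,
        "n_stability_subjects": cfg.n_stability_subjects,
        "stable_threshold": cfg.stable_threshold,
        "highly_stable_threshold": cfg.highly_stable_threshold,
        "extraction": cfg.extraction.to_dict(),
        "decisions": {
            "ring_distance_units": "voxels",
            "hu_window_mode": "resegmentation (voxel exclusion)",
            "welch_sinc_radius": 3,
            "delta_r": "mean over subjects of across-config CV, eps=1e-12",
            "pearson_prune_order": "descending variance",
            "lasso": "one-vs-rest, support union, 50-point log lambda grid",
            "test_set_convention": "inner 20% of each outer training portion",
            "clinical_in_variant5": "appended after selection, unpenalized",
        },
        "outputs": sorted(os.listdir(out)),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
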