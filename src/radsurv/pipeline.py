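"""End-to-end pipeline: cohort → features → selection → models → evaluation.

Three risk models are built on one shared train/test split and seed set —
clinical-only, radiomic-only, and combined — so paired bootstrap
comparisons between them are valid. Stages:

1. synthetic cohort generation (or user-supplied tables),
2. preprocessing + 593-feature radiomic extraction,
3. clinical covariate encoding (ordinal stages, indicator categories with
   explicit "missing" levels),
4. two-step feature selection on the training split,
5. network training per model variant,
6. test-split evaluation (C-index, time-dependent ROC, paired bootstrap),
7. Weibull reference curve + per-patient risk-of-progression periods.

Artifacts (CSV/JSON) are written under an output directory together with a
provenance manifest of the configuration and seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import risk as rk
from .deepsurv import HyperParams, RiskModel, predict_survival_curve, train
from .features.panel import extract_cohort
from .preprocess import resample_isotropic, wavelet_decompose, zscore_normalize
from .selection import (
    screen_clinical_pool,
    screen_radiomic_pool,
    sequential_forward_select,
)
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "split_cohort",
    "encode_clinical",
    "extract_radiomic_features",
    "run_pipeline",
]

logger = logging.getLogger("radsurv.pipeline")

MODEL_VARIANTS = ("clinical", "radiomic", "combined")


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    train_fraction: float = 0.70
    horizons: tuple[float, ...] = ev.DEFAULT_HORIZONS
    alpha: float = 0.1
    clinical_cap: int = 5
    radiomic_cap: int = 5
    radiomic_pool_cap: int = 25  # strongest screened features entering SFS
    hyperparams: HyperParams = field(default_factory=HyperParams)
    bootstrap_B: int = 1000
    split_seed: int = 101
    folds_seed: int = 202
    training_seed: int = 303
    bootstrap_seed: int = 404
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly inside (0, 1)")
        hs = list(self.horizons)
        if hs != sorted(hs) or len(set(hs)) != len(hs):
            raise ValueError("horizons must be strictly increasing")


def split_cohort(outcomes: pd.DataFrame, train_fraction: float = 0.70,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split of patient indices.

    Strata: censored patients, events below the median PFS, events above the
    median. Strata with fewer than 2 members fall back to event-only
    stratification (with a warning). |train| = floor(train_fraction * n).
    """
    n = len(outcomes)
    if n < 10:
        raise ValueError("need at least 10 patients to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly inside (0, 1): "
                         "both splits must be non-empty")
    T = outcomes["pfs_months"].to_numpy(dtype=np.float64)
    E = outcomes["event"].to_numpy(dtype=np.int64)
    med = np.median(T)
    strata = np.where(E == 0, 0, np.where(T <= med, 1, 2))
    counts = [int((strata == s).sum()) for s in np.unique(strata)]
    if min(counts) < 2:
        logger.warning("a PFS stratum has <2 patients; falling back to event-only strata")
        strata = E.copy()
    rng = np.random.default_rng(seed)
    n_train_total = int(np.floor(train_fraction * n))
    idx = np.arange(n)
    train_parts = []
    for s in np.unique(strata):
        g = idx[strata == s]
        g = g[rng.permutation(len(g))]
        k = int(round(train_fraction * len(g)))
        train_parts.append(g[:k])
    train_idx = np.sort(np.concatenate(train_parts))
    # reconcile rounding so |train| = floor(fraction * n) exactly
    while len(train_idx) > n_train_total:
        train_idx = np.delete(train_idx, rng.integers(0, len(train_idx)))
    while len(train_idx) < n_train_total:
        pool = np.setdiff1d(idx, train_idx)
        train_idx = np.sort(np.append(train_idx, pool[rng.integers(0, len(pool))]))
    test_idx = np.setdiff1d(idx, train_idx)
    return train_idx, test_idx


_CLINICAL_ORDINAL = {
    "n_stage": {"0": 0, "1": 1, "2": 2, "3": 3},
    "m_stage": {"0": 0, "1a": 1, "1b": 2, "1c": 3},
}


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the categorical clinical table.

    N and M stage become ordinals 0-3; histology a non-adeno indicator;
    laboratory variables expand to category indicators with an explicit
    missing level; smoking a yes indicator.
    """
    out = pd.DataFrame({"patient_id": clinical["patient_id"]})
    for col, mapping in _CLINICAL_ORDINAL.items():
        out[col] = clinical[col].map(mapping).astype(float)
    out["histology_nonadeno"] = (clinical["histology"] == "non-adeno").astype(float)
    for col, levels in (("total_protein", ("high", "low", "missing")),
                        ("mcv", ("high", "normal", "low", "missing"))):
        for lev in levels[1:]:  # first level is the reference
            out[f"{col}_{lev}"] = (clinical[col] == lev).astype(float)
    out["smoking_yes"] = (clinical["smoking"] == "yes").astype(float)
    return out


def extract_radiomic_features(cohort: SyntheticCohort) -> pd.DataFrame:
    """Preprocess every patient volume and extract the 593-feature panel."""
    if cohort.volumes is None or cohort.masks is None:
        raise ValueError("cohort carries no images; regenerate with include_images=True")
    banks, masks = [], []
    for vol, mask in zip(cohort.volumes, cohort.masks):
        v1, m1 = resample_isotropic(vol, mask)
        banks.append(wavelet_decompose(zscore_normalize(v1)))
        masks.append(m1)
    df = extract_cohort(banks, masks, cohort.clinical["patient_id"].tolist())
    return df.reset_index()


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    config: PipelineConfig
    features: pd.DataFrame            # radiomic + encoded clinical per patient
    outcomes: pd.DataFrame
    train_idx: np.ndarray
    test_idx: np.ndarray
    screens: pd.DataFrame
    panels: dict[str, list[str]]
    models: dict[str, RiskModel]
    metrics: pd.DataFrame             # per variant/horizon original metrics
    cindex: dict[str, float]
    comparisons: dict[str, pd.DataFrame]
    reference_curves: dict[str, rk.ReferenceRiskCurve]
    risk_reports: dict[str, pd.DataFrame]
    logrank: dict[str, tuple[float, float]]


def _drop_constant(cols: list[str], X: pd.DataFrame, idx: np.ndarray) -> list[str]:
    return [c for c in cols if X[c].to_numpy()[idx].std() > 0]


def run_pipeline(config: PipelineConfig,
                 cohort: SyntheticCohort | None = None,
                 radiomic_features: pd.DataFrame | None = None) -> PipelineResult:
    """Execute the full analysis; optionally reuse a cohort / feature matrix.

    All randomness flows from the seeds in ``config``; rerunning with the
    same config reproduces the result bit-for-bit.
    """
    t0 = time.time()
    if cohort is None:
        logger.info("generating synthetic cohort (n=%d)", config.cohort.n_patients)
        cohort = generate_cohort(config.cohort)
    outcomes = cohort.outcomes.reset_index(drop=True)

    if radiomic_features is None:
        logger.info("extracting radiomic features")
        radiomic_features = extract_radiomic_features(cohort)
    radiomic_features = radiomic_features.reset_index(drop=True)
    clin_enc = encode_clinical(cohort.clinical).reset_index(drop=True)
    radiomic_cols = [c for c in radiomic_features.columns if c != "patient_id"]
    clinical_cols = [c for c in clin_enc.columns if c != "patient_id"]
    features = radiomic_features.merge(clin_enc, on="patient_id")
    if not (features["patient_id"] == outcomes["patient_id"]).all():
        raise ValueError("feature and outcome tables disagree on patient order")

    train_idx, test_idx = split_cohort(outcomes, config.train_fraction, config.split_seed)
    tr_out = outcomes.iloc[train_idx].reset_index(drop=True)

    # --- screening (training split only) ---------------------------------
    logger.info("screening %d radiomic + %d clinical features", len(radiomic_cols),
                len(clinical_cols))
    rad_screen = screen_radiomic_pool(
        features.iloc[train_idx][radiomic_cols].reset_index(drop=True), tr_out,
        alpha=config.alpha)
    # the chi-squared screen works on the raw categorical table
    clin_raw_cols = [c for c in cohort.clinical.columns if c != "patient_id"]
    clin_screen = screen_clinical_pool(
        cohort.clinical.iloc[train_idx][clin_raw_cols].reset_index(drop=True), tr_out,
        alpha=config.alpha)
    screens = pd.DataFrame(
        [{"feature": r.feature, "pool": "radiomic", "statistic": r.statistic,
          "p_value": r.p_value, "kept": r.kept} for r in rad_screen]
        + [{"feature": r.feature, "pool": "clinical", "statistic": r.statistic,
            "p_value": r.p_value, "kept": r.kept} for r in clin_screen]
    )
    rad_kept = sorted((r for r in rad_screen if r.kept), key=lambda r: r.p_value)
    rad_pool = [r.feature for r in rad_kept[: config.radiomic_pool_cap]]
    clin_kept_raw = [r.feature for r in clin_screen if r.kept]
    # map kept raw clinical variables to their encoded columns
    clin_pool = [c for c in clinical_cols
                 if any(c == raw or c.startswith(f"{raw}_") for raw in clin_kept_raw)]
    rad_pool = _drop_constant(rad_pool, features, train_idx)
    clin_pool = _drop_constant(clin_pool, features, train_idx)

    # --- sequential forward selection per pool ----------------------------
    tr_feats = features.iloc[train_idx].reset_index(drop=True)
    panels: dict[str, list[str]] = {}
    for label, pool, cap in (("clinical", clin_pool, config.clinical_cap),
                             ("radiomic", rad_pool, config.radiomic_cap)):
        if pool:
            sel = sequential_forward_select(tr_feats, tr_out, pool, cap=cap,
                                            seed=config.folds_seed, pool_label=label)
            panels[label] = sel.features
        else:
            logger.warning("empty %s pool after screening", label)
            panels[label] = []
    panels["combined"] = panels["clinical"] + panels["radiomic"]
    logger.info("panels: %s", {k: len(v) for k, v in panels.items()})

    # --- model training ---------------------------------------------------
    models: dict[str, RiskModel] = {}
    for variant in MODEL_VARIANTS:
        cols = panels[variant]
        if not cols:
            continue
        hp = HyperParams(**{**asdict(config.hyperparams), "seed": config.training_seed})
        logger.info("training %s model on %d features", variant, len(cols))
        models[variant] = train(tr_feats, tr_out, hp, columns=cols)

    # --- evaluation on the test split ------------------------------------
    te_feats = features.iloc[test_idx].reset_index(drop=True)
    te_out = outcomes.iloc[test_idx].reset_index(drop=True)
    grid = np.arange(0.0, 31.0, 0.5)
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    metrics_rows = []
    cindex: dict[str, float] = {}
    reference_curves: dict[str, rk.ReferenceRiskCurve] = {}
    risk_reports: dict[str, pd.DataFrame] = {}
    logrank: dict[str, tuple[float, float]] = {}
    for variant, model in models.items():
        X_te = te_feats[model.feature_names].to_numpy(dtype=np.float64)
        h_te = model.predict_log_hazard(X_te)
        cindex[variant] = ev.concordance_index(h_te, te_out)
        tg, S = predict_survival_curve(model, X_te, grid)
        curves[variant] = (tg, S)
        anchors = []
        for hzn in config.horizons:
            j = int(np.argmin(np.abs(tg - hzn)))
            roc = ev.time_dependent_roc(S[:, j], te_out, hzn)
            metrics_rows.append(
                {"variant": variant, "horizon": hzn, "auc": roc.auc,
                 "sensitivity": roc.sensitivity, "specificity": roc.specificity,
                 "threshold": roc.optimal_threshold,
                 "n_cases": roc.n_cases, "n_controls": roc.n_controls}
            )
            anchors.append((hzn, roc.optimal_threshold))
        # risk-of-progression periods from the Weibull reference curve
        try:
            ref = rk.fit_weibull_reference(anchors)
        except ValueError as exc:
            logger.warning("%s: reference curve not fittable (%s)", variant, exc)
            continue
        reference_curves[variant] = ref
        reports = [
            rk.risk_period_report(pid, tg, S[i], ref)
            for i, pid in enumerate(te_out["patient_id"])
        ]
        risk_reports[variant] = pd.DataFrame(
            [{"patient_id": r.patient_id, "signed_area": r.signed_area,
              "negative_area": r.negative_area,
              "earliest_crossing": r.earliest_crossing, "category": r.category}
             for r in reports]
        )
        # log-rank: predicted-risk median split against observed outcomes
        groups = (h_te > np.median(h_te)).astype(int)
        if len(np.unique(groups)) == 2:
            logrank[variant] = ev.logrank_test(te_out, groups)

    metrics = pd.DataFrame(metrics_rows)

    comparisons: dict[str, pd.DataFrame] = {}
    for other in ("clinical", "radiomic"):
        if other in curves and "combined" in curves:
            comp = ev.bootstrap_compare(
                curves[other], curves["combined"], te_out,
                horizons=config.horizons, B=config.bootstrap_B,
                seed=config.bootstrap_seed)
            comparisons[f"{other}_vs_combined"] = comp.summary

    result = PipelineResult(
        config=config, features=features, outcomes=outcomes,
        train_idx=train_idx, test_idx=test_idx, screens=screens, panels=panels,
        models=models, metrics=metrics, cindex=cindex, comparisons=comparisons,
        reference_curves=reference_curves, risk_reports=risk_reports,
        logrank=logrank,
    )
    if config.outdir:
        _write_artifacts(result, Path(config.outdir))
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return result


def _write_artifacts(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.features.to_csv(outdir / "features.csv", index=False)
    res.outcomes.to_csv(outdir / "outcomes.csv", index=False)
    res.screens.to_csv(outdir / "screens.csv", index=False)
    res.metrics.to_csv(outdir / "metrics.csv", index=False)
    (outdir / "panels.json").write_text(json.dumps(res.panels, indent=2))
    for variant, model in res.models.items():
        model.save(outdir / f"model_{variant}.json")
    for name, df in res.comparisons.items():
        df.to_csv(outdir / f"bootstrap_{name}.csv", index=False)
    for variant, df in res.risk_reports.items():
        df.to_csv(outdir / f"risk_periods_{variant}.csv", index=False)
    refs = {v: {"shape": r.shape, "scale": r.scale, "anchors": r.anchors}
            for v, r in res.reference_curves.items()}
    (outdir / "reference_curves.json").write_text(json.dumps(refs, indent=2))
    manifest = {
        "config": {
            "cohort": asdict(res.config.cohort),
            "train_fraction": res.config.train_fraction,
            "horizons": list(res.config.horizons),
            "alpha": res.config.alpha,
            "caps": [res.config.clinical_cap, res.config.radiomic_cap],
            "hyperparams": asdict(res.config.hyperparams),
            "bootstrap_B": res.config.bootstrap_B,
            "seeds": {"split": res.config.split_seed, "folds": res.config.folds_seed,
                      "training": res.config.training_seed,
                      "bootstrap": res.config.bootstrap_seed},
        },
        "n_train": int(len(res.train_idx)),
        "n_test": int(len(res.test_idx)),
        "cindex": res.cindex,
        "logrank": {k: list(v) for k, v in res.logrank.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
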