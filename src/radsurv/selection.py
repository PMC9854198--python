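"""Two-step prognostic feature selection.

Step 1 — univariate screens on the training split only: a one-covariate Cox
proportional-hazards fit (Wald p) for each continuous radiomic feature, and
a Pearson chi-squared test against the good/poor tumor-control dichotomy for
each categorical clinical feature, both kept at p < 0.1. The permissive
threshold deliberately retains enough inputs for the downstream network.

Step 2 — greedy sequential forward selection (SFS) over each screened pool,
scored by cross-validated concordance of a multivariable Cox fit, stopping
at a configurable cap or when the score no longer improves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats

__all__ = [
    "ScreenResult",
    "SelectedPanel",
    "cox_screen",
    "chisq_screen",
    "screen_radiomic_pool",
    "screen_clinical_pool",
    "sequential_forward_select",
    "cv_cox_cindex",
]


@dataclass
class ScreenResult:
    feature: str
    statistic: float
    p_value: float
    kept: bool
    degenerate: bool = False


@dataclass
class SelectedPanel:
    features: list[str]
    score_trace: list[float]
    pool: str  # "clinical" | "radiomic"


def cox_screen(values: pd.Series | np.ndarray, outcomes: pd.DataFrame, alpha: float = 0.1,
               name: str | None = None) -> ScreenResult:
    """Univariate Cox proportional-hazards screen for one continuous feature.

    The feature is standardized before the fit; the Wald p-value decides
    retention. Zero-variance features are flagged degenerate and dropped.
    """
    x = np.asarray(values, dtype=np.float64)
    feat = name or (values.name if isinstance(values, pd.Series) else "feature")
    if outcomes["event"].sum() < 2:
        raise ValueError("Cox screen needs at least 2 events")
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        return ScreenResult(feat, 0.0, 1.0, False, degenerate=True)
    df = pd.DataFrame(
        {"x": (x - x.mean()) / sd,
         "pfs_months": outcomes["pfs_months"].to_numpy(),
         "event": outcomes["event"].to_numpy()}
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = CoxPHFitter().fit(df, duration_col="pfs_months", event_col="event")
        z = float(fit.summary.loc["x", "z"])
        p = float(fit.summary.loc["x", "p"])
    except ConvergenceError:
        return ScreenResult(feat, 0.0, 1.0, False, degenerate=True)
    return ScreenResult(feat, z, p, bool(p < alpha))


def dichotomize_control(outcomes: pd.DataFrame, median_pfs: float | None = None) -> pd.Series:
    """Good/poor tumor-control dichotomy at the (training) median PFS.

    Good control: PFS beyond the median; poor control: progression before the
    median. Patients censored before the median are indeterminate (NaN).
    """
    med = float(outcomes["pfs_months"].median()) if median_pfs is None else float(median_pfs)
    pfs = outcomes["pfs_months"].to_numpy()
    event = outcomes["event"].to_numpy()
    grp = np.where(pfs > med, 1.0, np.where(event == 1, 0.0, np.nan))
    return pd.Series(grp, index=outcomes.index, name="good_control")


def chisq_screen(values: pd.Series | np.ndarray, outcomes: pd.DataFrame, alpha: float = 0.1,
                 name: str | None = None, median_pfs: float | None = None) -> ScreenResult:
    """Pearson chi-squared screen of a categorical feature against tumor control."""
    feat = name or (values.name if isinstance(values, pd.Series) else "feature")
    cat = pd.Series(np.asarray(values, dtype=object))
    grp = dichotomize_control(outcomes, median_pfs).to_numpy()
    ok = ~pd.isna(grp)
    table = pd.crosstab(cat[ok].to_numpy(), grp[ok])
    if table.shape[0] < 2 or table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return ScreenResult(feat, 0.0, 1.0, False, degenerate=True)
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return ScreenResult(feat, float(chi2), float(p), bool(p < alpha))


def screen_radiomic_pool(features: pd.DataFrame, outcomes: pd.DataFrame,
                         alpha: float = 0.1) -> list[ScreenResult]:
    return [cox_screen(features[c], outcomes, alpha, name=c) for c in features.columns]


def screen_clinical_pool(clinical: pd.DataFrame, outcomes: pd.DataFrame, alpha: float = 0.1,
                         median_pfs: float | None = None) -> list[ScreenResult]:
    return [
        chisq_screen(clinical[c], outcomes, alpha, name=c, median_pfs=median_pfs)
        for c in clinical.columns
    ]


def cv_cox_cindex(features: pd.DataFrame, outcomes: pd.DataFrame, columns: list[str],
                  n_folds: int = 5, seed: int = 0) -> float:
    """Cross-validated Harrell C of a multivariable Cox fit on given columns."""
    n = len(features)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    cs = []
    X = features[columns].to_numpy(dtype=np.float64)
    T = outcomes["pfs_months"].to_numpy()
    E = outcomes["event"].to_numpy()
    for k in range(n_folds):
        test_idx = folds[k]
        train_idx = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        mu = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        df_tr = pd.DataFrame((X[train_idx] - mu) / sd, columns=columns)
        df_tr["pfs_months"] = T[train_idx]
        df_tr["event"] = E[train_idx]
        if df_tr["event"].sum() < 2:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = CoxPHFitter(penalizer=0.01).fit(
                    df_tr, duration_col="pfs_months", event_col="event"
                )
            risk = (X[test_idx] - mu) / sd @ fit.params_.to_numpy()
            cs.append(_lifelines_cindex(T[test_idx], -risk, E[test_idx]))
        except (ConvergenceError, ZeroDivisionError):
            continue
    if not cs:
        raise ValueError("cross-validated scoring failed on every fold")
    return float(np.mean(cs))


def sequential_forward_select(features: pd.DataFrame, outcomes: pd.DataFrame,
                              pool: list[str], cap: int = 5, scorer=None,
                              min_improvement: float = 0.01, seed: int = 0,
                              baseline_score: float | None = None,
                              pool_label: str = "radiomic") -> SelectedPanel:
    """Greedy forward selection maximizing the scorer at each step.

    The default scorer is 5-fold cross-validated Cox concordance with seeded
    fold assignment, so the search is deterministic. Selection stops when the
    cap is reached or the best candidate improves the running score by less
    than ``min_improvement``. For the default concordance scorer the empty
    model scores ``baseline_score = 0.5`` (chance), so the first feature must
    itself beat chance; the stop tolerance guards against the upward bias of
    maximizing a noisy cross-validated score over many candidates. Candidates
    on which the scorer fails are skipped with a warning.
    """
    if not pool:
        raise ValueError("candidate pool is empty")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if scorer is None:
        scorer = lambda cols: cv_cox_cindex(features, outcomes, cols, seed=seed)
        if baseline_score is None:
            baseline_score = 0.5  # concordance of a constant predictor
    selected: list[str] = []
    trace: list[float] = []
    best_score = -np.inf if baseline_score is None else float(baseline_score)
    remaining = list(dict.fromkeys(pool))
    while remaining and len(selected) < cap:
        step_best, step_feat = -np.inf, None
        for cand in remaining:
            try:
                s = scorer(selected + [cand])
            except Exception as exc:  # scorer failure: skip candidate
                warnings.warn(f"SFS scorer failed on {cand!r}: {exc}")
                continue
            if s > step_best:
                step_best, step_feat = s, cand
        if step_feat is None:
            break
        if step_best - best_score < min_improvement:
            break
        selected.append(step_feat)
        remaining.remove(step_feat)
        best_score = step_best
        trace.append(float(step_best))
    return SelectedPanel(selected, trace, pool_label)
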