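"""Model evaluation: concordance, time-dependent ROC, log-rank, bootstrap.

Time-dependent ROC uses the cumulative/dynamic definition at a horizon t:
cases progressed by t (T <= t with the event observed), controls are
progression-free beyond t (T > t), and patients censored before t are
excluded. The marker is the predicted survival probability S(t), with low
values classifying "progressed"; the optimal threshold maximizes the Youden
index (sensitivity + specificity - 1).

Paired model comparison draws bootstrap resamples of the test set, shared
between the two models, and applies a paired t-test per metric and horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "DEFAULT_HORIZONS",
    "TimeROC",
    "BootstrapComparison",
    "concordance_index",
    "roc_case_control",
    "time_dependent_roc",
    "logrank_test",
    "bootstrap_compare",
]

DEFAULT_HORIZONS = (3.0, 12.0, 18.0, 24.0)


def concordance_index(risk: np.ndarray, outcomes: pd.DataFrame) -> float:
    """Harrell's C over comparable pairs; score ties count 1/2.

    A pair is comparable when the strictly earlier observed time is an
    event; the pair is concordant when that earlier failure carries the
    higher risk score. Pairs with tied observed times are not comparable
    under this rule.
    """
    risk = np.asarray(risk, dtype=np.float64)
    T = outcomes["pfs_months"].to_numpy(dtype=np.float64)
    E = outcomes["event"].to_numpy(dtype=np.int64)
    ev = np.flatnonzero(E == 1)
    if ev.size == 0 or len(T) < 2:
        raise ValueError("concordance needs at least one comparable pair")
    later = T[None, :] > T[ev, None]          # j outlives event i
    conc = later & (risk[ev, None] > risk[None, :])
    tied = later & (risk[ev, None] == risk[None, :])
    n_comp = int(later.sum())
    if n_comp == 0:
        raise ValueError("concordance needs at least one comparable pair")
    return float((conc.sum() + 0.5 * tied.sum()) / n_comp)


@dataclass
class TimeROC:
    """Time-dependent ROC at one horizon."""

    horizon: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    optimal_threshold: float  # on the S(horizon) scale
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int


def roc_case_control(outcomes: pd.DataFrame, horizon: float):
    """(case, control, usable) boolean arrays at a horizon (cumulative/dynamic)."""
    T = outcomes["pfs_months"].to_numpy(dtype=np.float64)
    E = outcomes["event"].to_numpy(dtype=np.int64)
    case = (T <= horizon) & (E == 1)
    control = T > horizon
    return case, control, case | control


def time_dependent_roc(surv_at_horizon: np.ndarray, outcomes: pd.DataFrame,
                       horizon: float) -> TimeROC:
    """ROC for progression-by-horizon status with marker S(horizon).

    The staircase is swept over thresholds of the marker (low S => predicted
    progression); AUC by trapezoid equals the Mann-Whitney pair count.
    """
    s = np.asarray(surv_at_horizon, dtype=np.float64)
    case, control, usable = roc_case_control(outcomes, horizon)
    n_cases, n_controls = int(case.sum()), int(control.sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"horizon {horizon} months has {n_cases} cases and {n_controls} controls"
        )
    from sklearn.metrics import roc_curve

    y = case[usable].astype(int)
    score = -s[usable]  # low survival probability ranks as "progressed"
    fpr, tpr, thr = roc_curve(y, score, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    youden = tpr - fpr
    k = int(np.argmax(youden))
    # sklearn's first threshold is +inf sentinel; map back to the S scale
    s_star = float(np.clip(-thr[k], 1e-12, 1.0 - 1e-12))
    return TimeROC(
        horizon=float(horizon), fpr=fpr, tpr=tpr, auc=auc,
        optimal_threshold=s_star, sensitivity=float(tpr[k]),
        specificity=float(1.0 - fpr[k]), n_cases=n_cases, n_controls=n_controls,
    )


def logrank_test(outcomes: pd.DataFrame, groups: np.ndarray) -> tuple[float, float]:
    """Two-sample log-rank test; returns (statistic, p).

    If neither group has any event the test is uninformative and (0.0, 1.0)
    is returned with a warning.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly two non-empty groups, got {labels}")
    T = outcomes["pfs_months"].to_numpy(dtype=np.float64)
    E = outcomes["event"].to_numpy(dtype=np.int64)
    a, b = groups == labels[0], groups == labels[1]
    if E[a].sum() == 0 and E[b].sum() == 0:
        import warnings

        warnings.warn("log-rank: no events in either group; p set to 1")
        return 0.0, 1.0
    res = _ll_logrank(T[a], T[b], event_observed_A=E[a], event_observed_B=E[b])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class BootstrapComparison:
    """Paired bootstrap comparison of two models on one test set."""

    horizons: tuple[float, ...]
    n_replicates: int
    metrics_a: dict[str, np.ndarray]  # "<metric>@<horizon>" -> B values
    metrics_b: dict[str, np.ndarray]
    summary: pd.DataFrame  # mean/sd per model + paired t and p

    def mean(self, model: str, metric: str, horizon: float) -> float:
        key = f"{metric}@{horizon:g}"
        arr = self.metrics_a[key] if model == "a" else self.metrics_b[key]
        return float(arr.mean())


def _horizon_metrics(S_grid: np.ndarray, t_grid: np.ndarray, outcomes: pd.DataFrame,
                     horizon: float) -> tuple[float, float, float]:
    j = int(np.argmin(np.abs(t_grid - horizon)))
    roc = time_dependent_roc(S_grid[:, j], outcomes, horizon)
    return roc.auc, roc.sensitivity, roc.specificity


def bootstrap_compare(curves_a: tuple[np.ndarray, np.ndarray],
                      curves_b: tuple[np.ndarray, np.ndarray],
                      outcomes: pd.DataFrame,
                      horizons=DEFAULT_HORIZONS, B: int = 1000, seed: int = 0,
                      max_redraws: int = 100) -> BootstrapComparison:
    """Bootstrap the test set, shared between models, and paired-t compare.

    ``curves_a``/``curves_b`` are ``(t_grid, S)`` as returned by
    ``predict_survival_curve`` for the same test patients. Replicates in
    which some horizon has no case or no control are redrawn (logged via the
    redraw counter in the summary attrs).
    """
    if B < 2:
        raise ValueError("bootstrap comparison needs B >= 2")
    t_a, S_a = curves_a
    t_b, S_b = curves_b
    n = len(outcomes)
    if S_a.shape[0] != n or S_b.shape[0] != n:
        raise ValueError("curve matrices and outcomes disagree on patient count")
    rng = np.random.default_rng(seed)
    keys = [f"{m}@{h:g}" for h in horizons for m in ("auc", "sensitivity", "specificity")]
    met_a: dict[str, list[float]] = {k: [] for k in keys}
    met_b: dict[str, list[float]] = {k: [] for k in keys}
    redraws = 0
    out_reset = outcomes.reset_index(drop=True)
    for _ in range(B):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            boot_out = out_reset.iloc[idx].reset_index(drop=True)
            ok = True
            for h in horizons:
                case, control, _ = roc_case_control(boot_out, h)
                if case.sum() == 0 or control.sum() == 0:
                    ok = False
                    break
            if ok:
                break
            redraws += 1
        else:
            raise ValueError(
                f"could not draw a bootstrap replicate with cases and controls at "
                f"every horizon in {max_redraws} attempts"
            )
        for h in horizons:
            for tag, (tg, Sg) in (("a", (t_a, S_a)), ("b", (t_b, S_b))):
                auc, sens, spec = _horizon_metrics(Sg[idx], tg, boot_out, h)
                d = met_a if tag == "a" else met_b
                d[f"auc@{h:g}"].append(auc)
                d[f"sensitivity@{h:g}"].append(sens)
                d[f"specificity@{h:g}"].append(spec)
    arr_a = {k: np.array(v) for k, v in met_a.items()}
    arr_b = {k: np.array(v) for k, v in met_b.items()}
    rows = []
    for k in keys:
        if np.allclose(arr_a[k], arr_b[k]):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(arr_a[k], arr_b[k])
        metric, h = k.split("@")
        rows.append(
            {"metric": metric, "horizon": float(h),
             "mean_a": arr_a[k].mean(), "sd_a": arr_a[k].std(ddof=1),
             "mean_b": arr_b[k].mean(), "sd_b": arr_b[k].std(ddof=1),
             "t": float(t_stat), "p": float(p)}
        )
    summary = pd.DataFrame(rows)
    summary.attrs["redraws"] = redraws
    return BootstrapComparison(tuple(horizons), B, arr_a, arr_b, summary)
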