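"""Weibull reference risk curve and the risk-of-progression period.

The four horizon-specific optimal thresholds (S*, on the survival scale)
from the time-dependent ROC analysis anchor a Weibull survival curve

    S_ref(t) = exp(-(t / lam) ** k),

fitted by least squares after the complementary log-log linearization
log(-log S*) = k*log t - k*log lam (exact on Weibull-consistent anchors).

A patient's personalized curve is compared with the reference over the
observation window: the signed area between the curves summarizes overall
risk, and the earliest time at which the personalized curve drops below the
reference locates the risk-of-progression period within the checkpoint
partition (<3, 3-12, 12-18, 18-24, >24 months).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceRiskCurve",
    "RiskPeriodReport",
    "fit_weibull_reference",
    "risk_area",
    "classify_risk_period",
    "DEFAULT_CHECKPOINTS",
]

DEFAULT_CHECKPOINTS = (3.0, 12.0, 18.0, 24.0)


@dataclass
class ReferenceRiskCurve:
    """Weibull reference curve with its anchor points."""

    shape: float  # k
    scale: float  # lam, months
    anchors: list[tuple[float, float]]
    residuals: np.ndarray

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=np.float64)
        return np.exp(-((t / self.scale) ** self.shape))


def fit_weibull_reference(anchors) -> ReferenceRiskCurve:
    """Fit S_ref through (horizon, S*) anchors by complementary log-log
    least squares.

    Exactly recovers (k, lam) when the anchors lie on a Weibull curve.
    Anchors implying non-decreasing survival produce a non-positive shape
    and are rejected.
    """
    anchors = [(float(t), float(s)) for t, s in anchors]
    if len(anchors) < 2:
        raise ValueError("need at least two anchors to fit a Weibull curve")
    t = np.array([a[0] for a in anchors])
    s = np.array([a[1] for a in anchors])
    if np.any(t <= 0):
        raise ValueError("anchor horizons must be positive")
    if np.any((s <= 0) | (s >= 1)):
        raise ValueError("anchor thresholds must lie strictly inside (0, 1)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("anchor horizons must be strictly increasing")
    y = np.log(-np.log(s))
    x = np.log(t)
    A = np.stack([x, np.ones_like(x)], axis=1)
    (k, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    if k <= 0:
        raise ValueError(
            f"anchors imply non-decreasing survival (fitted shape {k:.3g}); "
            f"no decreasing Weibull curve passes through them"
        )
    lam = float(np.exp(-intercept / k))
    fitted = np.exp(-((t / lam) ** k))
    return ReferenceRiskCurve(float(k), lam, anchors, s - fitted)


@dataclass
class RiskPeriodReport:
    """Per-patient comparison against the reference risk curve."""

    patient_id: str
    signed_area: float
    negative_area: float
    below_intervals: list[tuple[float, float]]
    earliest_crossing: float | None
    category: str


def _interp_crossing(t0: float, t1: float, d0: float, d1: float) -> float:
    """Linear sign-change location of d = S_patient - S_ref between grid points."""
    if d1 == d0:
        return t0
    return t0 + (t1 - t0) * (-d0) / (d1 - d0)


def risk_area(t_grid: np.ndarray, s_patient: np.ndarray, ref: ReferenceRiskCurve,
              window: tuple[float, float] = (0.0, 24.0), step: float = 0.5):
    """Signed area between a personalized curve and the reference.

    The patient's step curve is carried right-continuously onto a fine grid
    over the window; the area uses the trapezoid rule and sub-intervals with
    S_patient < S_ref are located by linear interpolation of sign changes.
    Returns ``(signed_area, negative_area, below_intervals)``.
    """
    t_grid = np.asarray(t_grid, dtype=np.float64)
    s_patient = np.asarray(s_patient, dtype=np.float64)
    lo, hi = window
    if lo < t_grid[0] or hi > t_grid[-1]:
        raise ValueError(
            f"window {window} extends beyond the curve support "
            f"[{t_grid[0]:g}, {t_grid[-1]:g}]"
        )
    tt = np.arange(lo, hi + step / 2, step)
    idx = np.searchsorted(t_grid, tt, side="right") - 1
    sp = s_patient[np.clip(idx, 0, len(s_patient) - 1)]
    d = sp - np.asarray(ref(tt))
    signed = float(np.trapezoid(d, tt))
    negative = float(np.trapezoid(np.minimum(d, 0.0), tt))

    below: list[tuple[float, float]] = []
    inside = d[0] < 0
    start = tt[0] if inside else None
    for i in range(1, len(tt)):
        prev, cur = d[i - 1], d[i]
        if not inside and cur < 0 <= prev:
            start = _interp_crossing(tt[i - 1], tt[i], prev, cur)
            inside = True
        elif inside and cur >= 0 > prev:
            below.append((start, _interp_crossing(tt[i - 1], tt[i], prev, cur)))
            inside = False
    if inside:
        below.append((start, float(tt[-1])))
    return signed, negative, below


def classify_risk_period(below_intervals, window: tuple[float, float] = (0.0, 24.0),
                         checkpoints=DEFAULT_CHECKPOINTS) -> tuple[str, float | None]:
    """Risk-period category from the earliest time the patient curve dips
    below the reference.

    Returns ``(category, earliest_crossing)``; a curve never below the
    reference inside the window maps to ">24 months", one below from the
    window start to "<3 months".
    """
    cps = sorted(checkpoints)
    if not below_intervals:
        return f">{cps[-1]:g} months", None
    earliest = min(s for s, _ in below_intervals)
    if earliest <= window[0]:
        return f"<{cps[0]:g} months", earliest
    prev = window[0]
    for i, cp in enumerate(cps):
        if earliest < cp:
            if i == 0:
                return f"<{cp:g} months", earliest
            return f"{cps[i - 1]:g}-{cp:g} months", earliest
    return f">{cps[-1]:g} months", earliest


def risk_period_report(patient_id: str, t_grid: np.ndarray, s_patient: np.ndarray,
                       ref: ReferenceRiskCurve,
                       window: tuple[float, float] = (0.0, 24.0),
                       checkpoints=DEFAULT_CHECKPOINTS) -> RiskPeriodReport:
    """Full per-patient risk report (areas, crossings, category)."""
    signed, negative, below = risk_area(t_grid, s_patient, ref, window)
    category, earliest = classify_risk_period(below, window, checkpoints)
    return RiskPeriodReport(patient_id, signed, negative, below, earliest, category)
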