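"""Feed-forward Cox partial-likelihood network (DeepSurv-style risk model).

The network maps a standardized feature vector x to a scalar log relative
hazard h(x). Each hidden block applies batch normalization (learnable scale
and shift), ReLU, a fully connected layer, and dropout; the output layer is
a single linear node. With zero hidden blocks the model reduces exactly to
the Cox linear predictor w'x + b.

Training minimizes the average negative log Cox partial likelihood

    L = -(1/N_E) * sum_{i: event} [ h_i - log sum_{j: T_j >= T_i} exp(h_j) ]
        + l2_lambda * ||W||^2

with the Breslow convention for tied event times, full-batch Adam, a
1/(1 + decay * epoch) learning-rate schedule, and early stopping on an inner
validation split. Gradients are computed analytically (manual backprop);
everything is seeded and reproducible on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HyperParams",
    "RiskModel",
    "cox_partial_loss",
    "cox_loss_gradient",
    "train",
    "grid_search",
    "breslow_baseline",
    "predict_survival_curve",
    "DEFAULT_GRID",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class HyperParams:
    """Network and optimizer hyperparameters."""

    n_hidden_layers: int = 1
    nodes_per_layer: int = 32
    initial_lr: float = 0.01
    lr_decay: float = 0.01
    dropout_rate: float = 0.4
    l2_lambda: float = 1e-4
    max_epochs: int = 500
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.lr_decay < 0:
            raise ValueError("lr_decay must be >= 0")
        if self.n_hidden_layers > 0 and self.nodes_per_layer < 1:
            raise ValueError("nodes_per_layer must be >= 1")

    @property
    def n_parameters_per_input(self) -> int:
        """Rough parameter count (for grid-search tie-breaking)."""
        return self.n_hidden_layers * self.nodes_per_layer + 1


# ----------------------------------------------------------------- loss ---


def _risk_set_terms(h: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Sorted-time quantities shared by loss and gradient (Breslow ties)."""
    order = np.argsort(-times, kind="stable")
    t_s, h_s, e_s = times[order], h[order], events[order].astype(bool)
    n = len(t_s)
    # cumulative log-sum-exp of h over patients with T >= t (stabilized)
    lse = np.logaddexp.accumulate(h_s)
    # ties: the risk set of an event includes every patient with equal time
    last_idx = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        last_idx[i : j + 1] = j
        i = j + 1
    return order, t_s, h_s, e_s, lse, last_idx


def cox_partial_loss(h: np.ndarray, times: np.ndarray, events: np.ndarray,
                     l2_lambda: float = 0.0, weights: list[np.ndarray] | None = None) -> float:
    """Average negative log Cox partial likelihood (+ optional L2 penalty)."""
    h = np.asarray(h, dtype=np.float64).ravel()
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events)
    n_events = int(events.sum())
    if n_events < 1:
        raise ValueError("Cox partial likelihood needs at least one event")
    _, _, h_s, e_s, lse, last_idx = _risk_set_terms(h, times, events)
    loss = -float((h_s[e_s] - lse[last_idx[e_s]]).sum()) / n_events
    if l2_lambda and weights:
        loss += l2_lambda * float(sum((w**2).sum() for w in weights))
    return loss


def cox_loss_gradient(h: np.ndarray, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """d(average negative log partial likelihood) / d h, per patient."""
    h = np.asarray(h, dtype=np.float64).ravel()
    events = np.asarray(events)
    n_events = int(events.sum())
    if n_events < 1:
        raise ValueError("Cox partial likelihood needs at least one event")
    order, _, h_s, e_s, lse, last_idx = _risk_set_terms(h, np.asarray(times, float), events)
    n = len(h)
    contrib = np.zeros(n)
    np.add.at(contrib, last_idx[e_s], np.exp(-lse[last_idx[e_s]]))
    w = np.cumsum(contrib[::-1])[::-1]  # w_k = sum over events whose risk set includes k
    g_s = -(e_s.astype(np.float64) - np.exp(h_s) * w) / n_events
    g = np.empty(n)
    g[order] = g_s
    return g


# -------------------------------------------------------------- network ---


def _init_params(n_in: int, hp: HyperParams, rng: np.random.Generator) -> dict:
    params: dict[str, np.ndarray] = {}
    dim = n_in
    for l in range(hp.n_hidden_layers):
        params[f"gamma{l}"] = np.ones(dim)
        # shift init of +1 starts most units in the linear regime: the block
        # order (BN -> ReLU -> FC) would otherwise clip half of every
        # standardized input at initialization
        params[f"beta{l}"] = np.ones(dim)
        params[f"W{l}"] = rng.normal(0.0, np.sqrt(2.0 / dim), size=(dim, hp.nodes_per_layer))
        params[f"b{l}"] = np.zeros(hp.nodes_per_layer)
        dim = hp.nodes_per_layer
    params["w_out"] = rng.normal(0.0, np.sqrt(1.0 / dim), size=(dim, 1))
    params["b_out"] = np.zeros(1)
    return params


def _init_running(n_in: int, hp: HyperParams) -> dict:
    running: dict[str, np.ndarray] = {}
    dim = n_in
    for l in range(hp.n_hidden_layers):
        running[f"mean{l}"] = np.zeros(dim)
        running[f"var{l}"] = np.ones(dim)
        dim = hp.nodes_per_layer
    return running


def _forward(X: np.ndarray, params: dict, running: dict, hp: HyperParams,
             training: bool, dropout_rng: np.random.Generator | None = None):
    """Forward pass; returns (h, cache) with cache for backprop when training."""
    cache: list[dict] = []
    a = X
    for l in range(hp.n_hidden_layers):
        gamma, beta = params[f"gamma{l}"], params[f"beta{l}"]
        if training:
            mu = a.mean(axis=0)
            var = a.var(axis=0)
            running[f"mean{l}"] = (1 - _BN_MOMENTUM) * running[f"mean{l}"] + _BN_MOMENTUM * mu
            running[f"var{l}"] = (1 - _BN_MOMENTUM) * running[f"var{l}"] + _BN_MOMENTUM * var
        else:
            mu, var = running[f"mean{l}"], running[f"var{l}"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        x_hat = (a - mu) * inv_std
        u = gamma * x_hat + beta
        r = np.maximum(u, 0.0)
        z = r @ params[f"W{l}"] + params[f"b{l}"]
        if training and hp.dropout_rate > 0 and dropout_rng is not None:
            mask = (dropout_rng.random(z.shape) >= hp.dropout_rate) / (1.0 - hp.dropout_rate)
        else:
            mask = np.ones_like(z)
        zd = z * mask
        cache.append(
            {"a": a, "mu": mu, "inv_std": inv_std, "x_hat": x_hat, "u": u, "r": r,
             "mask": mask}
        )
        a = zd
    h = (a @ params["w_out"] + params["b_out"]).ravel()
    return h, {"blocks": cache, "last": a}


def _backward(dh: np.ndarray, params: dict, hp: HyperParams, fwd_cache: dict) -> dict:
    grads: dict[str, np.ndarray] = {}
    dh = dh.reshape(-1, 1)
    grads["w_out"] = fwd_cache["last"].T @ dh
    grads["b_out"] = dh.sum(axis=0)
    da = dh @ params["w_out"].T
    for l in reversed(range(hp.n_hidden_layers)):
        c = fwd_cache["blocks"][l]
        dz = da * c["mask"]
        grads[f"W{l}"] = c["r"].T @ dz
        grads[f"b{l}"] = dz.sum(axis=0)
        dr = dz @ params[f"W{l}"].T
        du = dr * (c["u"] > 0)
        grads[f"gamma{l}"] = (du * c["x_hat"]).sum(axis=0)
        grads[f"beta{l}"] = du.sum(axis=0)
        m = c["a"].shape[0]
        dx_hat = du * params[f"gamma{l}"]
        # batch-norm backward with batch statistics
        da = (
            dx_hat
            - dx_hat.mean(axis=0)
            - c["x_hat"] * (dx_hat * c["x_hat"]).mean(axis=0)
        ) * c["inv_std"]
    return grads


def _l2_weight_keys(params: dict) -> list[str]:
    return [k for k in params if k.startswith("W")] + ["w_out"]


@dataclass
class RiskModel:
    """A trained log-hazard network with its scaler and baseline survival."""

    hp: HyperParams
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    params: dict
    running: dict
    baseline_times: np.ndarray | None = None
    baseline_survival: np.ndarray | None = None
    history: pd.DataFrame | None = None

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return (X - self.scaler_mean) / self.scaler_sd

    def predict_log_hazard(self, X: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode h(x) (dropout off, stored BN stats)."""
        h, _ = _forward(self.standardize(X), self.params, self.running, self.hp,
                        training=False)
        return h

    # persistence -----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        blob = {
            "hp": asdict(self.hp),
            "feature_names": self.feature_names,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "running": {k: v.tolist() for k, v in self.running.items()},
            "baseline_times": None if self.baseline_times is None else self.baseline_times.tolist(),
            "baseline_survival": None if self.baseline_survival is None else self.baseline_survival.tolist(),
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "RiskModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            hp=HyperParams(**blob["hp"]),
            feature_names=blob["feature_names"],
            scaler_mean=np.array(blob["scaler_mean"]),
            scaler_sd=np.array(blob["scaler_sd"]),
            params={k: np.array(v) for k, v in blob["params"].items()},
            running={k: np.array(v) for k, v in blob["running"].items()},
            baseline_times=None if blob["baseline_times"] is None else np.array(blob["baseline_times"]),
            baseline_survival=None if blob["baseline_survival"] is None else np.array(blob["baseline_survival"]),
        )


def _stratified_split(events: np.ndarray, frac: float, rng: np.random.Generator):
    idx = np.arange(len(events))
    tr, va = [], []
    for grp in (0, 1):
        g = idx[events == grp]
        g = g[rng.permutation(len(g))]
        k = int(round(frac * len(g)))
        tr.append(g[:k])
        va.append(g[k:])
    return np.sort(np.concatenate(tr)), np.sort(np.concatenate(va))


def train(features: pd.DataFrame, outcomes: pd.DataFrame, hp: HyperParams,
          columns: list[str] | None = None, val_fraction: float = 0.2) -> RiskModel:
    """Fit the network by full-batch Adam with early stopping.

    An inner 80/20 split of the training data (stratified by event status)
    monitors validation loss; the best-epoch weights are restored. Full-batch
    gradients keep the partial-likelihood risk sets exact.
    """
    cols = columns or [c for c in features.columns if c != "patient_id"]
    X = features[cols].to_numpy(dtype=np.float64)
    T = outcomes["pfs_months"].to_numpy(dtype=np.float64)
    E = outcomes["event"].to_numpy(dtype=np.int64)
    if len(X) < 10:
        raise ValueError("training needs at least 10 patients")
    if E.sum() < 5:
        raise ValueError("training needs at least 5 events")

    rng = np.random.default_rng(hp.seed)
    tr_idx, va_idx = _stratified_split(E, 1.0 - val_fraction, rng)
    if E[va_idx].sum() < 1 or E[tr_idx].sum() < 1:
        raise ValueError("inner split left a part without events")

    mu = X[tr_idx].mean(axis=0)
    sd = X[tr_idx].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    params = _init_params(len(cols), hp, rng)
    running = _init_running(len(cols), hp)
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    l2_keys = set(_l2_weight_keys(params))

    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_running = {k: v.copy() for k, v in running.items()}
    stall = 0
    log = []
    t_adam = 0
    for epoch in range(hp.max_epochs):
        lr = hp.initial_lr / (1.0 + hp.lr_decay * epoch)
        h, cache = _forward(Xs[tr_idx], params, running, hp, training=True, dropout_rng=rng)
        if not np.all(np.isfinite(h)):
            raise FloatingPointError(f"training diverged (non-finite output) at epoch {epoch}, lr={lr:.2e}")
        dh = cox_loss_gradient(h, T[tr_idx], E[tr_idx])
        grads = _backward(dh, params, hp, cache)
        for k in l2_keys:
            grads[k] = grads[k] + 2.0 * hp.l2_lambda * params[k]
        t_adam += 1
        for k in params:
            adam_m[k] = b1 * adam_m[k] + (1 - b1) * grads[k]
            adam_v[k] = b2 * adam_v[k] + (1 - b2) * grads[k] ** 2
            m_hat = adam_m[k] / (1 - b1**t_adam)
            v_hat = adam_v[k] / (1 - b2**t_adam)
            params[k] = params[k] - lr * m_hat / (np.sqrt(v_hat) + eps)

        train_loss = cox_partial_loss(h, T[tr_idx], E[tr_idx], hp.l2_lambda,
                                      [params[k] for k in l2_keys])
        h_val, _ = _forward(Xs[va_idx], params, running, hp, training=False)
        if not np.all(np.isfinite(h_val)):
            raise FloatingPointError(f"training diverged (non-finite validation) at epoch {epoch}, lr={lr:.2e}")
        val_loss = cox_partial_loss(h_val, T[va_idx], E[va_idx])
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "lr": lr})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_running = {k: v.copy() for k, v in running.items()}
            stall = 0
        else:
            stall += 1
            if stall >= hp.patience:
                break

    model = RiskModel(
        hp=hp, feature_names=cols, scaler_mean=mu, scaler_sd=sd,
        params=best_params, running=best_running, history=pd.DataFrame(log),
    )
    breslow_baseline(features, outcomes, model, columns=cols)
    return model


DEFAULT_GRID: dict[str, list] = {
    "n_hidden_layers": [1, 2],
    "nodes_per_layer": [16, 32, 64],
    "initial_lr": [0.01, 0.001],
    "lr_decay": [0.01, 0.001],
    "dropout_rate": [0.2, 0.4],
}


def grid_search(features: pd.DataFrame, outcomes: pd.DataFrame,
                grid: dict[str, list] | None = None, columns: list[str] | None = None,
                seed: int = 0, **fixed) -> tuple[HyperParams, pd.DataFrame]:
    """Exhaustive hyperparameter search scored by inner-validation C-index.

    Each combination is trained with the shared seed; the winner maximizes
    the concordance of evaluation-mode risk scores on the inner validation
    split. Ties break toward fewer parameters, then lower learning rate.
    Returns the winning HyperParams and the full trace.
    """
    from lifelines.utils import concordance_index

    grid = grid or DEFAULT_GRID
    keys = list(grid)
    if any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid has an empty axis")
    combos: list[dict] = [{}]
    for k in keys:
        combos = [dict(c, **{k: v}) for c in combos for v in grid[k]]

    cols = columns or [c for c in features.columns if c != "patient_id"]
    E = outcomes["event"].to_numpy(dtype=np.int64)
    T = outcomes["pfs_months"].to_numpy(dtype=np.float64)
    rows = []
    failures = []
    for combo in combos:
        hp = HyperParams(seed=seed, **{**fixed, **combo})
        try:
            model = train(features, outcomes, hp, columns=cols)
        except (ValueError, FloatingPointError) as exc:
            failures.append((combo, str(exc)))
            continue
        rng = np.random.default_rng(seed)
        _, va_idx = _stratified_split(E, 0.8, rng)
        h_val = model.predict_log_hazard(features[cols].to_numpy()[va_idx])
        try:
            c = concordance_index(T[va_idx], -h_val, E[va_idx])
        except ZeroDivisionError:
            failures.append((combo, "no comparable validation pairs"))
            continue
        rows.append({**combo, "val_cindex": float(c),
                     "n_params": hp.n_parameters_per_input})
    if not rows:
        raise RuntimeError(f"every grid combination failed: {failures}")
    trace = pd.DataFrame(rows)
    ranked = trace.sort_values(
        by=["val_cindex", "n_params", "initial_lr"],
        ascending=[False, True, True],
        kind="stable",
    )
    best = ranked.iloc[0]
    hp = HyperParams(seed=seed, **{**fixed, **{k: best[k] for k in keys}})
    # restore python scalar types lost through pandas
    hp.n_hidden_layers = int(hp.n_hidden_layers)
    hp.nodes_per_layer = int(hp.nodes_per_layer)
    return hp, trace


def breslow_baseline(features: pd.DataFrame, outcomes: pd.DataFrame, model: RiskModel,
                     columns: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimator of the baseline survival S0(t) on the training data.

    H0(t) = sum_{event times t_k <= t} d_k / sum_{j in R(t_k)} exp(h_j);
    S0 = exp(-H0), a right-continuous non-increasing step function with
    S0(0) = 1. The curve is stored on the model.
    """
    cols = columns or model.feature_names
    h = model.predict_log_hazard(features[cols].to_numpy(dtype=np.float64))
    T = outcomes["pfs_months"].to_numpy(dtype=np.float64)
    E = outcomes["event"].to_numpy(dtype=np.int64)
    exp_h = np.exp(h)
    event_times = np.unique(T[E == 1])
    increments = np.empty_like(event_times)
    for k, t in enumerate(event_times):
        d_k = int(((T == t) & (E == 1)).sum())
        increments[k] = d_k / exp_h[T >= t].sum()
    H0 = np.cumsum(increments)
    model.baseline_times = event_times
    model.baseline_survival = np.exp(-H0)
    return event_times, model.baseline_survival


def predict_survival_curve(model: RiskModel, X: np.ndarray,
                           grid_months: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Personalized survival curves S(t) = S0(t) ** exp(h(x)).

    Returns ``(t_grid, S)`` with S shaped (n_patients, len(t_grid)); the
    baseline step function is carried right-continuously onto the grid
    (monthly 0..30 by default).
    """
    if model.baseline_times is None or model.baseline_survival is None:
        raise ValueError("model has no baseline survival; call breslow_baseline first")
    if grid_months is None:
        grid_months = np.arange(0.0, 31.0)
    h = model.predict_log_hazard(X)
    idx = np.searchsorted(model.baseline_times, grid_months, side="right") - 1
    s0 = np.where(idx >= 0, model.baseline_survival[np.clip(idx, 0, None)], 1.0)
    S = s0[None, :] ** np.exp(h)[:, None]
    return grid_months, S
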