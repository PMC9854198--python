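"""Cox partial-likelihood network: loss, gradients, training, baseline."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, NelsonAalenFitter

from radsurv.deepsurv import (
    HyperParams,
    breslow_baseline,
    cox_loss_gradient,
    cox_partial_loss,
    grid_search,
    predict_survival_curve,
    train,
)
from radsurv.deepsurv import _backward, _forward, _init_params, _init_running
from radsurv.evaluation import concordance_index

from conftest import make_outcomes


class TestLoss:
    def test_zero_scores_closed_form(self):
        # all h=0, n events at distinct times: risk sets n, n-1, ..., 1
        for n in (3, 7, 20):
            L = cox_partial_loss(np.zeros(n), np.arange(1.0, n + 1), np.ones(n, int))
            assert L == pytest.approx(np.mean(np.log(np.arange(1, n + 1))))

    def test_single_event_is_penalty_only(self):
        L = cox_partial_loss(np.array([3.7]), np.array([5.0]), np.array([1]))
        assert L == pytest.approx(0.0)
        L2 = cox_partial_loss(np.array([3.7]), np.array([5.0]), np.array([1]),
                              l2_lambda=0.1, weights=[np.array([2.0])])
        assert L2 == pytest.approx(0.4)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_partial_loss(np.zeros(4), np.arange(4.0), np.zeros(4, int))

    @pytest.mark.parametrize("seed", range(4))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        h = rng.normal(size=n)
        T = rng.uniform(1, 20, n)
        if seed == 2:  # exercise the Breslow tie path
            T[:4] = T[0]
        E = (rng.random(n) < 0.7).astype(int)
        E[rng.integers(n)] = 1
        g = cox_loss_gradient(h, T, E)
        for i in range(n):
            hp_, hm = h.copy(), h.copy()
            hp_[i] += 1e-6
            hm[i] -= 1e-6
            fd = (cox_partial_loss(hp_, T, E) - cox_partial_loss(hm, T, E)) / 2e-6
            assert abs(g[i] - fd) < 1e-5


class TestNetwork:
    def test_zero_weights_zero_output(self):
        hp = HyperParams(n_hidden_layers=1, nodes_per_layer=4, dropout_rate=0.0)
        params = _init_params(3, hp, np.random.default_rng(0))
        for k in params:
            params[k] = np.zeros_like(params[k])
        h, _ = _forward(np.random.default_rng(1).normal(size=(5, 3)), params,
                        _init_running(3, hp), hp, training=False)
        np.testing.assert_array_equal(h, np.zeros(5))

    def test_zero_hidden_layers_is_linear(self, tabular_cohort):
        feats, _, out, _ = tabular_cohort
        cols = ["latent_compactness", "latent_texture"]
        hp = HyperParams(n_hidden_layers=0, dropout_rate=0.0, max_epochs=5, seed=0)
        model = train(feats.iloc[:100].reset_index(drop=True),
                      out.iloc[:100].reset_index(drop=True), hp, columns=cols)
        X = np.array([[0.3, -1.2], [2.0, 0.5]])
        w = model.params["w_out"].ravel()
        b = model.params["b_out"][0]
        expected = model.standardize(X) @ w + b
        np.testing.assert_allclose(model.predict_log_hazard(X), expected, atol=1e-12)

    def test_forward_deterministic_and_dimension_checked(self, tabular_cohort):
        feats, _, out, _ = tabular_cohort
        cols = ["latent_compactness", "latent_texture", "noise_0"]
        model = train(feats.iloc[:120].reset_index(drop=True),
                      out.iloc[:120].reset_index(drop=True),
                      HyperParams(max_epochs=30, seed=1), columns=cols)
        X = np.random.default_rng(2).normal(size=(4, 3))
        h1 = model.predict_log_hazard(X)
        h2 = model.predict_log_hazard(X)
        np.testing.assert_array_equal(h1, h2)
        np.testing.assert_array_equal(
            model.predict_log_hazard(np.vstack([X, X]))[:4], h1)
        with pytest.raises(ValueError, match="features"):
            model.predict_log_hazard(np.zeros((2, 5)))

    @pytest.mark.parametrize("n_layers", [1, 2])
    def test_backprop_matches_finite_differences(self, n_layers):
        rng = np.random.default_rng(3)
        hp = HyperParams(n_hidden_layers=n_layers, nodes_per_layer=4,
                         dropout_rate=0.0, seed=1)
        X = rng.normal(size=(8, 3))
        T = rng.uniform(1, 20, 8)
        E = np.ones(8, int)
        params = _init_params(3, hp, np.random.default_rng(4))
        running = _init_running(3, hp)

        def loss():
            h, _ = _forward(X, params, {k: v.copy() for k, v in running.items()},
                            hp, training=True)
            return cox_partial_loss(h, T, E)

        h, cache = _forward(X, params, {k: v.copy() for k, v in running.items()},
                            hp, training=True)
        grads = _backward(cox_loss_gradient(h, T, E), params, hp, cache)
        for k, v in params.items():
            it = np.nditer(v, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = v[i]
                v[i] = orig + 1e-6
                lp = loss()
                v[i] = orig - 1e-6
                lm = loss()
                v[i] = orig
                assert abs(grads[k][i] - (lp - lm) / 2e-6) < 1e-5, k


class TestTraining:
    def test_matches_cox_oracle_on_linear_data(self, tabular_cohort):
        feats, _, out, _ = tabular_cohort
        cols = ["latent_compactness", "latent_texture", "noise_0", "noise_1"]
        tr = np.arange(280)
        te = np.arange(280, 400)
        f_tr = feats.iloc[tr].reset_index(drop=True)
        o_tr = out.iloc[tr].reset_index(drop=True)
        o_te = out.iloc[te].reset_index(drop=True)
        model = train(f_tr, o_tr, HyperParams(seed=3), columns=cols)
        c_net = concordance_index(
            model.predict_log_hazard(feats.iloc[te][cols].to_numpy()), o_te)
        df = f_tr[cols].copy()
        df["pfs_months"] = o_tr["pfs_months"]
        df["event"] = o_tr["event"]
        cph = CoxPHFitter().fit(df, "pfs_months", "event")
        c_cox = concordance_index(
            feats.iloc[te][cols].to_numpy() @ cph.params_.to_numpy(), o_te)
        assert abs(c_net - c_cox) <= 0.03

    def test_null_data_chance_concordance(self, null_tabular_cohort):
        feats, _, out, _ = null_tabular_cohort
        cols = ["latent_compactness", "latent_texture", "noise_0", "noise_1"]
        tr = np.arange(1400)
        te = np.arange(1400, 2000)
        model = train(feats.iloc[tr].reset_index(drop=True),
                      out.iloc[tr].reset_index(drop=True),
                      HyperParams(seed=3), columns=cols)
        c = concordance_index(
            model.predict_log_hazard(feats.iloc[te][cols].to_numpy()),
            out.iloc[te].reset_index(drop=True))
        assert 0.45 <= c <= 0.55

    def test_same_seed_identical_weights(self, tabular_cohort):
        feats, _, out, _ = tabular_cohort
        cols = ["latent_compactness", "latent_texture"]
        f = feats.iloc[:150].reset_index(drop=True)
        o = out.iloc[:150].reset_index(drop=True)
        m1 = train(f, o, HyperParams(seed=9, max_epochs=60), columns=cols)
        m2 = train(f, o, HyperParams(seed=9, max_epochs=60), columns=cols)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_loss_decreases_early(self, tabular_cohort):
        feats, _, out, _ = tabular_cohort
        cols = ["latent_compactness", "latent_texture"]
        model = train(feats.iloc[:200].reset_index(drop=True),
                      out.iloc[:200].reset_index(drop=True),
                      HyperParams(seed=2, max_epochs=40), columns=cols)
        losses = model.history["train_loss"].to_numpy()
        assert losses[5:15].mean() < losses[0]

    def test_preconditions(self, tabular_cohort):
        feats, _, out, _ = tabular_cohort
        cols = ["latent_compactness"]
        with pytest.raises(ValueError, match="10 patients"):
            train(feats.iloc[:5].reset_index(drop=True),
                  out.iloc[:5].reset_index(drop=True), HyperParams(), columns=cols)


class TestGridSearch:
    def test_singleton_grid_returned(self, tabular_cohort):
        feats, _, out, _ = tabular_cohort
        cols = ["latent_compactness", "latent_texture"]
        grid = {"n_hidden_layers": [1], "nodes_per_layer": [8],
                "initial_lr": [0.01], "lr_decay": [0.01], "dropout_rate": [0.2]}
        hp, trace = grid_search(feats.iloc[:150].reset_index(drop=True),
                                out.iloc[:150].reset_index(drop=True),
                                grid, columns=cols, seed=1, max_epochs=40)
        assert hp.nodes_per_layer == 8 and hp.n_hidden_layers == 1
        assert len(trace) == 1

    def test_winner_maximizes_validation_concordance(self, tabular_cohort):
        feats, _, out, _ = tabular_cohort
        cols = ["latent_compactness", "latent_texture", "noise_0"]
        grid = {"n_hidden_layers": [0, 1], "nodes_per_layer": [8],
                "initial_lr": [0.01], "lr_decay": [0.01], "dropout_rate": [0.0, 0.4]}
        hp, trace = grid_search(feats.iloc[:200].reset_index(drop=True),
                                out.iloc[:200].reset_index(drop=True),
                                grid, columns=cols, seed=2, max_epochs=60)
        winner = trace.sort_values("val_cindex", ascending=False).iloc[0]
        assert trace["val_cindex"].max() == pytest.approx(winner["val_cindex"])
        assert hp.n_hidden_layers == int(winner["n_hidden_layers"])

    def test_empty_grid_axis_rejected(self, tabular_cohort):
        feats, _, out, _ = tabular_cohort
        with pytest.raises(ValueError, match="empty"):
            grid_search(feats, out, {"n_hidden_layers": []})


class TestBaselineAndCurves:
    @pytest.fixture(scope="class")
    def fitted(self, tabular_cohort):
        feats, _, out, _ = tabular_cohort
        cols = ["latent_compactness", "latent_texture"]
        f = feats.iloc[:200].reset_index(drop=True)
        o = out.iloc[:200].reset_index(drop=True)
        model = train(f, o, HyperParams(seed=4, max_epochs=100), columns=cols)
        return f, o, cols, model

    def test_zero_hazard_reduces_to_nelson_aalen(self, fitted):
        f, o, cols, model = fitted
        import copy

        m0 = copy.deepcopy(model)
        for k in m0.params:
            m0.params[k] = np.zeros_like(m0.params[k])
        times, s0 = breslow_baseline(f, o, m0, columns=cols)
        na = NelsonAalenFitter().fit(o["pfs_months"], o["event"])
        H_na = na.cumulative_hazard_.loc[times].to_numpy().ravel()
        np.testing.assert_allclose(-np.log(s0), H_na, atol=1e-10)

    def test_baseline_monotone_from_one(self, fitted):
        _, _, _, model = fitted
        s0 = model.baseline_survival
        assert np.all(np.diff(s0) <= 1e-12)
        assert s0[0] <= 1.0
        # S0 before the first event time is 1 by construction of the grid
        t, S = predict_survival_curve(model, np.zeros((1, 2)),
                                      np.array([0.0, 50.0]))
        assert S[0, 0] == pytest.approx(1.0)

    def test_breslow_scale_equivariance(self, fitted):
        f, o, cols, model = fitted
        import copy

        _, s0 = breslow_baseline(f, o, model, columns=cols)
        shifted = copy.deepcopy(model)
        shifted.params["b_out"] = shifted.params["b_out"] + np.log(2.0)
        _, s0_shift = breslow_baseline(f, o, shifted, columns=cols)
        # doubling every exp(h) halves each Breslow increment
        np.testing.assert_allclose(-np.log(s0_shift), -np.log(s0) / 2.0, rtol=1e-9)

    def test_curve_reduces_to_baseline_at_zero_hazard(self, fitted):
        f, o, cols, model = fitted
        import copy

        m0 = copy.deepcopy(model)
        for k in m0.params:
            m0.params[k] = np.zeros_like(m0.params[k])
        breslow_baseline(f, o, m0, columns=cols)
        grid = np.arange(0.0, 31.0)
        _, S = predict_survival_curve(m0, np.zeros((1, len(cols))), grid)
        idx = np.searchsorted(m0.baseline_times, grid, side="right") - 1
        expected = np.where(idx >= 0, m0.baseline_survival[np.clip(idx, 0, None)], 1.0)
        np.testing.assert_allclose(S[0], expected)

    def test_curves_ordered_and_never_cross(self, fitted):
        f, o, cols, model = fitted
        X = f[cols].to_numpy()[:30]
        h = model.predict_log_hazard(X)
        t, S = predict_survival_curve(model, X)
        order = np.argsort(h)
        for a, b in zip(order, order[1:]):
            assert np.all(S[a] >= S[b] - 1e-12)  # lower hazard: higher curve

    def test_missing_baseline_rejected(self, fitted):
        f, o, cols, model = fitted
        import copy

        m = copy.deepcopy(model)
        m.baseline_times = None
        with pytest.raises(ValueError, match="baseline"):
            predict_survival_curve(m, np.zeros((1, len(cols))))

    def test_model_roundtrip(self, fitted, tmp_path):
        f, o, cols, model = fitted
        model.save(tmp_path / "model.json")
        from radsurv.deepsurv import RiskModel

        loaded = RiskModel.load(tmp_path / "model.json")
        X = f[cols].to_numpy()[:10]
        np.testing.assert_allclose(loaded.predict_log_hazard(X),
                                   model.predict_log_hazard(X), atol=1e-12)
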