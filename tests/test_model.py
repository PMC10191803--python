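"""Occurrence model: covariate scaling, eNN covariate, Laplace fit vs
penalized-IRLS and MCMC oracles, WAIC arithmetic, significance flags."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import spdesdm as s
from spdesdm.model import NN_COLUMN


class TestScaleCovariates:
    def test_z_scores(self):
        dm = s.scale_covariates(pd.DataFrame({"v": [1.0, 2.0, 3.0]}))
        col = dm.values["v"].to_numpy()
        np.testing.assert_allclose(col, np.array([-1.0, 0.0, 1.0]) / np.std([1.0, 2.0, 3.0]))
        assert abs(col.mean()) <= 1e-12 and abs(col.std() - 1.0) <= 1e-12
        assert dm.scaling["v"] == (2.0, pytest.approx(np.std([1.0, 2.0, 3.0])))

    def test_constant_column_names_offender(self):
        df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            s.scale_covariates(df)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame({"v": rng.normal(5, 2, 100)})
        dm = s.scale_covariates(train)
        new = pd.DataFrame({"v": rng.normal(5, 2, 50)})
        scaled = dm.apply(new)
        back = dm.invert("v", scaled["v"].to_numpy())
        np.testing.assert_allclose(back, new["v"].to_numpy(), atol=1e-12)


class TestNNCovariate:
    def test_two_presences(self):
        pres = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
        vals = s.nn_covariate(pres, pres)
        np.testing.assert_allclose(vals, np.log(1 + 5.0))

    def test_background_on_presence_is_zero(self):
        pres = np.array([[0.0, 0.0], [1.0, 0.0]])
        pts = np.array([[0.0, 0.0], [0.5, 0.0]])
        vals = s.nn_covariate(pts, pres, is_presence=[False, False])
        # the coincident background point has raw value log(1) = 0
        assert vals[0] == 0.0
        np.testing.assert_allclose(vals[1], np.log(1.5))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        pres = rng.uniform(0, 10, size=(40, 2))
        pts = rng.uniform(0, 10, size=(200, 2))
        fast = s.nn_covariate(pts, pres)
        brute = np.log1p(
            [min(np.linalg.norm(p - q) for q in pres) for p in pts]
        )
        np.testing.assert_allclose(fast, brute, atol=1e-12)

    def test_single_presence_rejected(self):
        with pytest.raises(ValueError):
            s.nn_covariate(np.zeros((3, 2)), np.array([[0.0, 0.0]]))


class TestFit:
    def test_intercept_only_recovers_logit_half(self):
        z = np.array([1] * 500 + [0] * 500)
        dm = s.DesignMatrix(pd.DataFrame(index=range(1000)), {})
        f = s.fit(s.ModelSpec((), include_rf=False), dm, z)
        assert abs(f.beta.loc["intercept", "mean"]) <= 0.1

    def test_matches_penalized_irls_oracle(self, logistic_data):
        dm, z = logistic_data
        f = s.fit(s.ModelSpec(("a", "b", "c"), include_rf=False), dm, z)
        # independent IRLS oracle with the matching Gaussian prior (sd 10)
        X = np.column_stack([np.ones(len(z)), dm.values.to_numpy()])
        P = np.eye(4) / 100.0
        beta = np.zeros(4)
        for _ in range(100):
            mu = expit(X @ beta)
            g = X.T @ (z - mu) - P @ beta
            if np.abs(g).max() < 1e-12:
                break
            H = (X.T * (mu * (1 - mu))) @ X + P
            beta = beta + np.linalg.solve(H, g)
        np.testing.assert_allclose(f.beta["mean"].to_numpy(), beta, atol=1e-4)

    def test_fitted_probabilities_in_unit_interval(self, logistic_data):
        dm, z = logistic_data
        f = s.fit(s.ModelSpec(("a",), include_rf=False), dm, z)
        p = f.fitted_probabilities
        assert np.all((p > 0) & (p < 1))

    def test_rf_fit_field_finite_and_quantiles_ordered(self, small_spde, small_mesh):
        rng = np.random.default_rng(11)
        n = 400
        pts = rng.uniform(0, 30, (n, 2))
        dm = s.scale_covariates(pd.DataFrame({"a": rng.standard_normal(n)}))
        fld = s.simulate_grf_at(pts, 10.0, 1.0, rng)
        z = (rng.random(n) < expit(0.3 + dm.values["a"].to_numpy() + fld)).astype(int)
        A = s.projector(small_mesh, pts)
        f = s.fit(
            s.ModelSpec(("a",)), dm, z, small_spde, A, hyper_grid=[(10.0, 1.0)], seed=2
        )
        assert np.all(np.isfinite(f.field_mean))
        assert len(f.field_mean) == small_mesh.n_vertices
        b = f.beta
        assert (b["q2.5"] <= b["q50"]).all() and (b["q50"] <= b["q97.5"]).all()
        assert f.loglik_draws.shape[1] == n

    def test_laplace_close_to_mcmc_oracle(self, small_spde, small_mesh):
        # posterior beta means from the Gaussian approximation vs a seeded
        # independence-Metropolis chain
        rng = np.random.default_rng(21)
        n = 350
        pts = rng.uniform(0, 30, (n, 2))
        dm = s.scale_covariates(pd.DataFrame({"a": rng.standard_normal(n)}))
        fld = s.simulate_grf_at(pts, 10.0, 0.8, rng)
        z = (rng.random(n) < expit(-0.4 + 0.9 * dm.values["a"].to_numpy() + fld)).astype(int)
        A = s.projector(small_mesh, pts)
        kw = dict(hyper_grid=[(10.0, 0.8)], seed=5)
        lap = s.fit(s.ModelSpec(("a",)), dm, z, small_spde, A, **kw)
        mc = s.fit(
            s.ModelSpec(("a",)), dm, z, small_spde, A, method="mcmc",
            mcmc_iters=6000, mcmc_burn=1000, **kw,
        )
        diff = np.abs(lap.beta["mean"].to_numpy() - mc.beta["mean"].to_numpy())
        assert diff.max() <= 0.05

    def test_nn_column_required_when_enabled(self, logistic_data):
        dm, z = logistic_data
        with pytest.raises(ValueError, match=NN_COLUMN):
            s.fit(s.ModelSpec(("a",), include_rf=False, include_nn=True), dm, z)

    def test_bad_labels_rejected(self, logistic_data):
        dm, _ = logistic_data
        with pytest.raises(ValueError, match="0/1"):
            s.fit(s.ModelSpec(("a",), include_rf=False), dm, np.full(len(dm), 2))


class TestWAIC:
    def test_degenerate_posterior(self):
        ll = np.tile(np.array([-0.3, -1.2, -0.7]), (4, 1))
        w, p, lppd = s.waic(ll)
        assert p == 0.0
        np.testing.assert_allclose(w, -2 * ll[0].sum())

    def test_hand_computation_3x4(self):
        # 3 observations x 4 draws, computed by hand with plain loops
        ll = np.array(
            [
                [-0.5, -1.0, -0.2],
                [-0.7, -0.9, -0.4],
                [-0.6, -1.1, -0.3],
                [-0.4, -1.2, -0.5],
            ]
        )
        import math

        lppd_hand = sum(
            math.log(sum(math.exp(ll[s_, i]) for s_ in range(4)) / 4.0)
            for i in range(3)
        )
        p_hand = 0.0
        for i in range(3):
            col = [ll[s_, i] for s_ in range(4)]
            m = sum(col) / 4.0
            p_hand += sum((v - m) ** 2 for v in col) / 3.0
        w, p, lppd = s.waic(ll)
        np.testing.assert_allclose(lppd, lppd_hand, atol=1e-12)
        np.testing.assert_allclose(p, p_hand, atol=1e-12)
        np.testing.assert_allclose(w, -2 * (lppd_hand - p_hand), atol=1e-12)

    def test_true_covariate_lowers_waic(self):
        # adding the data-generating covariate to an intercept-only model
        # lowers WAIC in nearly all replicates
        rng = np.random.default_rng(0)
        wins = 0
        n_rep = 60
        for _ in range(n_rep):
            n = 300
            x = rng.standard_normal(n)
            z = (rng.random(n) < expit(-0.2 + 1.2 * x)).astype(int)
            dm = s.scale_covariates(pd.DataFrame({"x": x}))
            f0 = s.fit(s.ModelSpec((), include_rf=False), dm, z, seed=1)
            f1 = s.fit(s.ModelSpec(("x",), include_rf=False), dm, z, seed=1)
            wins += f1.waic < f0.waic
        assert wins >= 0.9 * n_rep

    def test_waic_invariant_to_column_order_and_row_relabeling(self, logistic_data):
        dm, z = logistic_data
        f_ab = s.fit(s.ModelSpec(("a", "b"), include_rf=False), dm, z, n_draws=2000, seed=3)
        f_ba = s.fit(s.ModelSpec(("b", "a"), include_rf=False), dm, z, n_draws=2000, seed=3)
        assert abs(f_ab.waic - f_ba.waic) <= 1.0
        perm = np.random.default_rng(0).permutation(len(z))
        dm_p = s.DesignMatrix(dm.values.iloc[perm].reset_index(drop=True), dm.scaling)
        f_p = s.fit(s.ModelSpec(("a", "b"), include_rf=False), dm_p, z[perm], n_draws=2000, seed=3)
        assert abs(f_ab.waic - f_p.waic) <= 1.0

    def test_nonfinite_pointwise_likelihood_lists_indices(self):
        ll = np.zeros((3, 5))
        ll[1, 2] = np.inf
        with pytest.raises(ValueError, match="2"):
            s.waic(ll)

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            s.waic(np.zeros((1, 5)))


class TestSignificance:
    def test_positive_interval_informative(self):
        assert s.interval_informative(0.09, 0.26) is True

    def test_interval_straddling_zero_uninformative(self):
        assert s.interval_informative(-0.12, 0.40) is False
        assert s.interval_informative(-1.0, 1.0) is False

    def test_flags_from_fit(self, logistic_data):
        dm, z = logistic_data
        f = s.fit(s.ModelSpec(("a", "b", "c"), include_rf=False), dm, z)
        sig = s.significance(f)
        # strong true effects (-1, 0.8, -0.5) at n=2000 are all informative
        assert sig.loc[["a", "b", "c"], "informative"].all()
        assert (sig["lower"] <= sig["upper"]).all()
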