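import numpy as np
import pandas as pd
import pytest

import gkblup as gk
from gkblup.gblup import _env_design, build_design


def _oracle_inputs(fit, K, records):
    """Total genetic covariance and fixed-effect surface for oracle checks."""
    dsg = build_design(records, K.line_ids)
    C1 = dsg.Z_g @ K.K @ dsg.Z_g.T
    Om = gk.build_gxe_covariance(dsg.Z_E, dsg.Z_g, K)
    C = fit.var_g * C1 + fit.var_ge * Om
    m = _env_design(records["env"].astype(str).tolist(), fit._env_labels) @ fit._beta_mean
    return C, m


class TestBuildGxECovariance:
    def test_identity_kernel_crossed_design(self):
        # 2 lines x 2 environments, K = I: only same-line/same-env cells survive
        Z_E = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        Z_g = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        Om = gk.build_gxe_covariance(Z_E, Z_g, np.eye(2))
        assert np.allclose(Om, np.eye(4))

    def test_hand_hadamard_single_env(self):
        Z_E = np.ones((2, 1))
        Z_g = np.eye(2)
        K = np.array([[1.0, 0.5], [0.5, 1.0]])
        Om = gk.build_gxe_covariance(Z_E, Z_g, K)
        assert np.allclose(Om, [[1.0, 0.5], [0.5, 1.0]])

    def test_cross_environment_cells_are_zero(self):
        Z_E = np.array([[1, 0], [0, 1]], dtype=float)
        Z_g = np.array([[1, 0], [1, 0]], dtype=float)  # same line, different envs
        K = np.array([[1.0, 0.9], [0.9, 1.0]])
        Om = gk.build_gxe_covariance(Z_E, Z_g, K)
        assert Om[0, 1] == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gk.build_gxe_covariance(np.ones((3, 1)), np.eye(2), np.eye(2))


class TestConditionalMeanOracle:
    def test_zero_genetic_covariance_returns_fixed_surface(self):
        C = np.zeros((3, 3))
        m = np.array([1.0, 2.0, 3.0])
        out = gk.conditional_mean_oracle(np.array([5.0, 6.0]), C, 1.0, m, [2])
        assert out == pytest.approx([3.0])

    def test_two_train_one_test_hand_solve(self):
        # covariances set by hand; compare against the written-out 2x2 solve
        C = np.array([
            [1.0, 0.3, 0.5],
            [0.3, 1.0, 0.2],
            [0.5, 0.2, 1.0],
        ])
        ve = 0.5
        y_tr = np.array([2.0, -1.0])
        m = np.array([0.5, 0.5, 0.5])
        A = np.array([[1.5, 0.3], [0.3, 1.5]])
        alpha = np.linalg.solve(A, y_tr - 0.5)
        expected = 0.5 + np.array([0.5, 0.2]) @ alpha
        out = gk.conditional_mean_oracle(y_tr, C, ve, m, [2])
        assert out == pytest.approx([expected], abs=1e-12)

    def test_interpolates_duplicated_record_in_noiseless_limit(self):
        # test record shares its covariance row with a training record
        K = np.array([[1.0, 0.4], [0.4, 1.0]])
        C = np.array([
            [1.0, 0.4, 1.0],
            [0.4, 1.0, 0.4],
            [1.0, 0.4, 1.0],
        ])
        y_tr = np.array([3.0, 1.0])
        m = np.zeros(3)
        out = gk.conditional_mean_oracle(y_tr, C, 1e-10, m, [2])
        assert out == pytest.approx([3.0], abs=1e-3)

    def test_permutation_equivariance(self, small_dataset, small_kernel):
        """Jointly permuting records leaves conditional-mean predictions
        unchanged (exchangeability of the model)."""
        ph = small_dataset.phenotypes.reset_index(drop=True)
        K = small_kernel
        dsg = build_design(ph, K.line_ids)
        C1 = dsg.Z_g @ K.K @ dsg.Z_g.T
        Om = gk.build_gxe_covariance(dsg.Z_E, dsg.Z_g, K)
        C = 1.0 * C1 + 0.4 * Om
        y = ph["value"].to_numpy()
        m = np.full(len(ph), 5.0)
        test_idx = np.arange(5)
        base = gk.conditional_mean_oracle(y[5:], C, 0.6, m, test_idx)
        perm = np.random.default_rng(0).permutation(len(ph))
        Cp = C[np.ix_(perm, perm)]
        test_pos = np.where(np.isin(perm, test_idx))[0]
        train_pos = np.setdiff1d(np.arange(len(ph)), test_pos)
        out_p = gk.conditional_mean_oracle(
            y[perm[train_pos]], Cp, 0.6, m[perm], test_pos)
        back = dict(zip(perm[test_pos], out_p))
        assert np.allclose([back[t] for t in test_idx], base, atol=1e-8)


@pytest.fixture(scope="module")
def masked_fit():
    """J=30 dataset with 10 masked records, fit plus held-out frame."""
    cfg = gk.SimulationConfig(J=30, p=80, I=2, rho_true=0.2, seed=11)
    ds = gk.simulate_dataset(cfg)
    ph = ds.phenotypes.reset_index(drop=True)
    rng = np.random.default_rng(5)
    mask = rng.choice(len(ph), 10, replace=False)
    train = ph.drop(index=mask).reset_index(drop=True)
    test = ph.iloc[mask].reset_index(drop=True)
    K = gk.gaussian_kernel(gk.squared_distance_matrix(ds.markers), 0.2)
    spec = gk.ModelSpec(n_iter=12000, burn_in=2000, thin=5, seed=7)
    fit = gk.fit_gibbs(train, K, spec)
    return fit, K, train, test


class TestFitGibbs:
    def test_seed_determinism(self, small_dataset, small_kernel):
        spec = gk.ModelSpec(n_iter=1500, burn_in=500, thin=5, seed=99)
        f1 = gk.fit_gibbs(small_dataset.phenotypes, small_kernel, spec)
        f2 = gk.fit_gibbs(small_dataset.phenotypes, small_kernel, spec)
        assert np.array_equal(f1.yhat_train, f2.yhat_train)
        assert f1.samples.equals(f2.samples)
        assert f1.mu_hat == f2.mu_hat

    def test_retained_draw_count(self, small_dataset, small_kernel):
        spec = gk.ModelSpec(n_iter=1501, burn_in=500, thin=7, seed=1)
        fit = gk.fit_gibbs(small_dataset.phenotypes, small_kernel, spec)
        assert fit.n_samples == (1501 - 500) // 7

    def test_variances_positive_throughout_chain(self, small_dataset, small_kernel):
        spec = gk.ModelSpec(n_iter=1500, burn_in=100, thin=1, seed=3)
        fit = gk.fit_gibbs(small_dataset.phenotypes, small_kernel, spec)
        assert (fit.samples > 0).all().all()

    def test_constant_phenotype_shrinks_to_constant(self, small_kernel):
        lines = list(small_kernel.line_ids)
        ph = pd.DataFrame({"line": lines, "env": "E1", "value": 4.2})
        spec = gk.ModelSpec(n_iter=2000, burn_in=500, thin=5, seed=2)
        fit = gk.fit_gibbs(ph, small_kernel, spec)
        sd = np.sqrt(fit.var_g + fit.var_ge + fit.var_e)
        assert np.all(np.abs(fit.yhat_train - 4.2) < 2 * sd + 1e-6)
        assert fit.var_g < 1e-4 and fit.var_ge < 1e-4

    def test_unknown_line_rejected(self, small_kernel):
        ph = pd.DataFrame({"line": ["ghost"], "env": ["E1"], "value": [1.0]})
        with pytest.raises(KeyError, match="ghost"):
            gk.fit_gibbs(ph, small_kernel, gk.ModelSpec(n_iter=20, burn_in=0, thin=1))

    def test_balanced_and_general_paths_agree(self, small_dataset, small_kernel):
        """The Kronecker fast path and the generic eigenbasis path sample the
        same posterior: long-run summaries agree closely."""
        ph = small_dataset.phenotypes.reset_index(drop=True)
        spec = gk.ModelSpec(n_iter=24000, burn_in=4000, thin=4, seed=21)
        bal = gk.fit_gibbs(ph, small_kernel, spec, method="balanced")
        gen = gk.fit_gibbs(ph, small_kernel, spec, method="general")
        assert np.allclose(bal.yhat_train, gen.yhat_train, atol=0.1)
        assert bal.mu_hat == pytest.approx(gen.mu_hat, abs=0.05)
        for a, b in [(bal.var_g, gen.var_g), (bal.var_ge, gen.var_ge),
                     (bal.var_e, gen.var_e)]:
            assert a == pytest.approx(b, rel=0.3, abs=0.05)

    def test_general_method_refused_nothing_balanced_requires(self, small_dataset, small_kernel):
        ph = small_dataset.phenotypes.reset_index(drop=True).iloc[:-3]
        with pytest.raises(ValueError, match="balanced"):
            gk.fit_gibbs(ph, small_kernel, gk.ModelSpec(n_iter=50, burn_in=10, thin=1),
                         method="balanced")


class TestPredict:
    def test_training_record_reproduces_fitted_value(self, masked_fit):
        fit, K, train, _ = masked_fit
        rec = train.iloc[[3]][["line", "env"]]
        pred = gk.predict(fit, K, rec)
        assert pred["y_hat"].iloc[0] == pytest.approx(fit.yhat_train[3], abs=1e-8)

    def test_zero_genetic_variance_predicts_fixed_effects(self, masked_fit, small_kernel):
        fit, K, train, test = masked_fit
        import copy
        f0 = copy.copy(fit)
        f0._d1_mean = np.zeros_like(fit._d1_mean)
        f0._d2_mean = np.zeros_like(fit._d2_mean)
        pred = gk.predict(f0, K, test[["line", "env"]])
        expected = fit.mu_hat + fit.env_effects[test["env"].astype(str)].to_numpy()
        assert np.allclose(pred["y_hat"], expected, atol=1e-10)

    def test_line_absent_from_kernel_rejected(self, masked_fit):
        fit, K, _, _ = masked_fit
        with pytest.raises(KeyError, match="stranger"):
            gk.predict(fit, K, pd.DataFrame({"line": ["stranger"], "env": ["E1"]}))

    def test_unseen_environment_rejected(self, masked_fit):
        fit, K, train, _ = masked_fit
        rec = pd.DataFrame({"line": [train["line"].iloc[0]], "env": ["E9"]})
        with pytest.raises(ValueError, match="E9"):
            gk.predict(fit, K, rec)


class TestGibbsAgainstOracle:
    def test_masked_records_match_oracle(self, masked_fit):
        """Posterior predictive means track the closed-form conditional mean
        evaluated at the posterior-mean variance components."""
        fit, K, train, test = masked_fit
        pred = gk.predict(fit, K, test[["line", "env"]])
        allrec = pd.concat([train, test], ignore_index=True)
        C, m = _oracle_inputs(fit, K, allrec)
        test_idx = np.arange(len(train), len(allrec))
        oracle = gk.conditional_mean_oracle(
            train["value"].to_numpy(), C, fit.var_e, m, test_idx)
        r = np.corrcoef(pred["y_hat"], oracle)[0, 1]
        assert r > 0.95
        assert np.sqrt(np.mean((pred["y_hat"].to_numpy() - oracle) ** 2)) < 0.02

    def test_discrepancy_shrinks_with_chain_length(self, small_dataset, small_kernel):
        ph = small_dataset.phenotypes.reset_index(drop=True)
        train = ph.iloc[:-8]
        test = ph.iloc[-8:]
        allrec = pd.concat([train, test], ignore_index=True)
        rmses = {}
        for n_iter in (2000, 20000):
            spec = gk.ModelSpec(n_iter=n_iter, burn_in=n_iter // 4, thin=2, seed=31)
            fit = gk.fit_gibbs(train, small_kernel, spec)
            pred = gk.predict(fit, small_kernel, test[["line", "env"]])
            C, m = _oracle_inputs(fit, small_kernel, allrec)
            oracle = gk.conditional_mean_oracle(
                train["value"].to_numpy(), C, fit.var_e, m,
                np.arange(len(train), len(allrec)))
            rmses[n_iter] = np.sqrt(np.mean((pred["y_hat"].to_numpy() - oracle) ** 2))
        assert rmses[20000] < rmses[2000]


class TestVarianceRecovery:
    def test_posterior_means_near_truth_across_replicates(self):
        """Simulation at variance ratio 1 : 0.5 : 0.5 recovers each component
        within 50% relative error in at least 80% of replicates."""
        ok = 0
        n_rep = 20
        for s in range(n_rep):
            cfg = gk.SimulationConfig(J=200, p=100, I=2, rho_true=0.2,
                                      var_g=1.0, var_ge=0.5, var_e=0.5,
                                      seed=500 + s)
            ds = gk.simulate_dataset(cfg)
            K = gk.gaussian_kernel(gk.squared_distance_matrix(ds.markers), 0.2)
            spec = gk.ModelSpec(n_iter=5000, burn_in=1000, thin=5, seed=s)
            fit = gk.fit_gibbs(ds.phenotypes, K, spec)
            ok += all(
                abs(v - t) / t <= 0.5
                for v, t in [(fit.var_g, 1.0), (fit.var_ge, 0.5), (fit.var_e, 0.5)]
            )
        assert ok >= 0.8 * n_rep


class TestModelSpecValidation:
    @pytest.mark.parametrize("kw", [
        {"n_iter": 100, "burn_in": 100},
        {"thin": 0},
        {"prior_df": 0},
        {"prior_R2": 1.5},
        {"n_iter": 10, "burn_in": 8, "thin": 5},
    ])
    def test_bad_settings_rejected(self, kw):
        with pytest.raises(ValueError):
            gk.ModelSpec(**kw)
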