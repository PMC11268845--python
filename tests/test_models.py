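"""Prediction models: BLUP algebra, Bayesian samplers vs closed forms and
quadrature, ML tuning contract."""

import numpy as np
import pandas as pd
import pytest

from phenopred.containers import GenotypeMatrix, KinshipMatrix
from phenopred.models import tester_design as make_tester_design
from phenopred.kinship import gaussian_kernels, vanraden_grm
from phenopred.models import (
    ChainSettings,
    MLModelSpec,
    fit_bayesian_lasso,
    fit_blup,
    fit_rkhs_ka,
    intercept_design,
    predict,
    tune_and_fit_ml,
)


def marker_panel(rng, n=60, m=150):
    ids = [f"H{i:03d}" for i in range(n)]
    D = rng.integers(0, 3, size=(n, m)).astype(float)
    return GenotypeMatrix(ids, [f"m{j}" for j in range(m)], D)


def additive_trait(rng, gm, h2=0.6):
    beta = rng.normal(size=gm.m) * 0.2
    g = (gm.dosages - gm.dosages.mean(0)) @ beta
    e = rng.normal(scale=np.sqrt(g.var() * (1 - h2) / h2), size=gm.n)
    return pd.Series(g + e, index=gm.ids, name="t"), g


class TestBlup:
    def test_identity_kinship_matches_ridge_closed_form(self, rng):
        n = 30
        ids = [f"i{k}" for k in range(n)]
        y = pd.Series(rng.normal(size=n), index=ids, name="t")
        K = KinshipMatrix(ids, np.eye(n))
        lam = 2.5
        model = fit_blup(y, intercept_design(ids), [K], fixed_ratios={"additive": lam})
        V = np.eye(n) + lam * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        beta = float(
            np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y.to_numpy()).item()
        )
        u = lam * Vi @ (y.to_numpy() - beta)
        np.testing.assert_allclose(model.effects["additive"].to_numpy(), u, atol=1e-8)
        assert model.result.beta[0] == pytest.approx(beta, rel=1e-8)

    def test_constant_response(self, rng):
        gm = marker_panel(rng, n=25)
        K = vanraden_grm(gm)
        y = pd.Series(4.2, index=gm.ids, name="t")
        model = fit_blup(y, intercept_design(gm.ids), [K])
        assert model.result.beta[0] == pytest.approx(4.2, abs=1e-6)
        np.testing.assert_allclose(model.effects["additive"], 0.0, atol=1e-5)

    def test_gblup_equals_rrblup_50x200(self, rng):
        """Marker-effect ridge and kinship BLUP are the same linear model."""
        gm = marker_panel(rng, n=50, m=200)
        y, _ = additive_trait(rng, gm)
        train = gm.ids[:40]
        K = vanraden_grm(gm)
        model = fit_blup(y.loc[train], intercept_design(gm.ids), [K])
        lam = model.varcomps["additive"] / model.varcomps["residual"]
        p = gm.allele_frequencies()
        Z = gm.dosages - 2 * p
        c = 2 * np.sum(p * (1 - p))
        Zt = Z[:40]
        yc = y.loc[train].to_numpy() - model.result.beta[0]
        alpha = Zt.T @ np.linalg.solve(lam / c * (Zt @ Zt.T) + np.eye(40), lam * yc) / c
        pred_rr = Z @ alpha + model.result.beta[0]
        np.testing.assert_allclose(predict(model, gm.ids), pred_rr, atol=1e-6)

    def test_shift_invariance(self, rng):
        gm = marker_panel(rng, n=30)
        y, _ = additive_trait(rng, gm)
        K = vanraden_grm(gm)
        fd = intercept_design(gm.ids)
        m0 = fit_blup(y, fd, [K])
        m1 = fit_blup(y + 100.0, fd, [K])
        np.testing.assert_allclose(
            predict(m1, gm.ids), predict(m0, gm.ids) + 100.0, atol=1e-4
        )

    def test_combined_with_zero_spectral_variance_is_gblup(self, rng):
        gm = marker_panel(rng, n=30)
        y, _ = additive_trait(rng, gm)
        Ka = vanraden_grm(gm)
        Kw = KinshipMatrix(gm.ids, np.eye(gm.n), kind="nirs")
        lam = 1.0
        single = fit_blup(y, intercept_design(gm.ids), [Ka], fixed_ratios={"additive": lam})
        combined = fit_blup(
            y,
            intercept_design(gm.ids),
            [Ka, Kw],
            fixed_ratios={"additive": lam, "nirs": 1e-12},
        )
        np.testing.assert_allclose(
            predict(combined, gm.ids), predict(single, gm.ids), atol=1e-6
        )

    def test_training_individual_prediction_is_fitted_value(self, rng):
        gm = marker_panel(rng, n=20)
        y, _ = additive_trait(rng, gm)
        model = fit_blup(y, intercept_design(gm.ids), [vanraden_grm(gm)])
        fitted = model.fixed.rows([gm.ids[3]]) @ model.result.beta + model.effects.iloc[3].sum()
        assert predict(model, [gm.ids[3]])[0] == pytest.approx(float(fitted.item()))

    def test_permuting_test_order_permutes_output(self, rng):
        gm = marker_panel(rng, n=20)
        y, _ = additive_trait(rng, gm)
        model = fit_blup(y.iloc[:15], intercept_design(gm.ids), [vanraden_grm(gm)])
        ids = gm.ids[15:]
        fwd = predict(model, ids)
        np.testing.assert_allclose(predict(model, ids[::-1]), fwd[::-1])

    def test_clone_of_training_individual(self, rng):
        """Identical kinship row implies an identical genetic prediction."""
        gm = marker_panel(rng, n=20)
        clone = GenotypeMatrix(
            gm.ids + ["clone"],
            list(gm.markers),
            np.vstack([gm.dosages, gm.dosages[0]]),
        )
        K = vanraden_grm(clone)
        y, _ = additive_trait(rng, gm)
        model = fit_blup(y, intercept_design(clone.ids), [K])
        assert predict(model, ["clone"])[0] == pytest.approx(
            predict(model, [gm.ids[0]])[0], abs=1e-8
        )

    def test_unknown_individual_raises(self, rng):
        gm = marker_panel(rng, n=20)
        y, _ = additive_trait(rng, gm)
        model = fit_blup(y, intercept_design(gm.ids), [vanraden_grm(gm)])
        with pytest.raises(KeyError):
            predict(model, ["nope"])

    def test_tester_design_column(self):
        testers = pd.Series(["M1", "M2", "M1"], index=["a", "b", "c"])
        fd = make_tester_design(testers)
        assert fd.names == ["intercept", "tester:M2"]
        np.testing.assert_array_equal(fd.rows(["a", "b"]), [[1.0, 0.0], [1.0, 1.0]])


class TestBayesianLasso:
    def test_single_marker_quadrature_oracle(self, rng):
        """Gibbs posterior mean of one effect vs 2-D numerical integration."""
        n = 25
        x = rng.normal(size=n)
        a_true = 0.8
        sigma_e = 0.5
        y_vec = a_true * x + rng.normal(scale=sigma_e, size=n) + 1.0
        ids = [f"i{k}" for k in range(n)]
        y = pd.Series(y_vec, index=ids, name="t")
        M = pd.DataFrame({"x": x}, index=ids)
        lam = 2.0
        fit = fit_bayesian_lasso(
            y,
            intercept_design(ids),
            marker_matrix=M,
            settings=ChainSettings(n_iter=6000, burn_in=1000, thin=2, seed=3),
            fix_sigma_e2=sigma_e**2,
            fix_lambda=lam,
        )
        # oracle: posterior ~ N(y | b + x a, sigma_e^2) * exp(-lam |a| / sigma_e)
        bs = np.linspace(-3, 5, 401)
        as_ = np.linspace(-3, 5, 401)
        B, A = np.meshgrid(bs, as_, indexing="ij")
        ll = np.zeros_like(B)
        for i, b in enumerate(bs):
            r = y_vec[None, :] - b - np.outer(as_, x)
            ll[i] = -0.5 * np.sum(r * r, axis=1) / sigma_e**2
        logw = ll - lam * np.abs(A) / sigma_e
        w = np.exp(logw - logw.max())
        post_mean = float((A * w).sum() / w.sum())
        post_sd = float(np.sqrt((A * A * w).sum() / w.sum() - post_mean**2))
        mc_se = post_sd / np.sqrt(fit.diagnostics["n_samples"] / 10.0)
        assert fit.effects["markers"][0] == pytest.approx(post_mean, abs=3 * mc_se + 1e-3)

    def test_huge_lambda_shrinks_to_fixed_effect_fit(self, rng):
        n = 30
        ids = [f"i{k}" for k in range(n)]
        y = pd.Series(rng.normal(size=n) + 2.0, index=ids, name="t")
        M = pd.DataFrame(rng.normal(size=(n, 5)), index=ids)
        fit = fit_bayesian_lasso(
            y,
            intercept_design(ids),
            marker_matrix=M,
            settings=ChainSettings(n_iter=2000, burn_in=500, thin=2, seed=1),
            fix_lambda=1e6,
        )
        np.testing.assert_allclose(fit.effects["markers"], 0.0, atol=1e-3)
        assert fit.beta[0] == pytest.approx(y.mean(), abs=0.05)

    def test_seeded_chains_identical(self, rng):
        n = 20
        ids = [f"i{k}" for k in range(n)]
        y = pd.Series(rng.normal(size=n), index=ids, name="t")
        M = pd.DataFrame(rng.normal(size=(n, 4)), index=ids)
        s = ChainSettings(n_iter=500, burn_in=100, thin=1, seed=9)
        f1 = fit_bayesian_lasso(y, intercept_design(ids), marker_matrix=M, settings=s)
        f2 = fit_bayesian_lasso(y, intercept_design(ids), marker_matrix=M, settings=s)
        np.testing.assert_array_equal(f1.effects["markers"], f2.effects["markers"])
        np.testing.assert_array_equal(f1.beta, f2.beta)

    def test_chain_shorter_than_burnin_rejected(self):
        with pytest.raises(ValueError):
            ChainSettings(n_iter=100, burn_in=100)

    def test_normal_prior_collapses_to_ridge(self, rng):
        """With fixed-variance normal priors the sampler targets the ridge
        posterior; its mean must match the closed form."""
        n, p = 40, 8
        ids = [f"i{k}" for k in range(n)]
        M = pd.DataFrame(rng.normal(size=(n, p)), index=ids)
        y = pd.Series(M.to_numpy() @ rng.normal(size=p) + rng.normal(size=n), index=ids, name="t")
        sigma_e2, tau2 = 1.0, 0.5
        fit = fit_bayesian_lasso(
            y,
            intercept_design(ids),
            marker_matrix=M,
            settings=ChainSettings(n_iter=8000, burn_in=2000, thin=2, seed=4),
            fix_sigma_e2=sigma_e2,
            prior="normal",
            normal_tau2=tau2,
        )
        X = np.column_stack([np.ones(n), M.to_numpy()])
        D = np.diag([0.0] + [1.0 / tau2] * p)
        coef = np.linalg.solve(X.T @ X + D, X.T @ y.to_numpy())
        assert fit.beta[0] == pytest.approx(coef[0], abs=0.05)
        np.testing.assert_allclose(fit.effects["markers"], coef[1:], atol=0.05)


class TestRKHS:
    def test_single_kernel_matches_kernel_ridge(self, rng):
        n = 40
        ids = [f"i{k}" for k in range(n)]
        feats = rng.normal(size=(n, 20))
        (K,) = gaussian_kernels(feats, ids, bandwidths=(0.5,))
        y = pd.Series(rng.normal(size=n), index=ids, name="t")
        lam = 1.5
        fit = fit_rkhs_ka(
            y,
            intercept_design(ids),
            [K],
            settings=ChainSettings(n_iter=4000, burn_in=1000, thin=2, seed=2),
            fix_ratios=[lam],
        )
        V = np.eye(n) + lam * K.values
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        beta = float(np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y.to_numpy()).item())
        u = lam * K.values @ Vi @ (y.to_numpy() - beta)
        pred_closed = beta + u
        np.testing.assert_allclose(predict(fit, ids), pred_closed, atol=0.1)
        assert np.corrcoef(predict(fit, ids), pred_closed)[0, 1] > 0.999

    def test_three_identical_kernels_equal_single(self, rng):
        n = 30
        ids = [f"i{k}" for k in range(n)]
        feats = rng.normal(size=(n, 15))
        (K,) = gaussian_kernels(feats, ids, bandwidths=(0.5,))
        y = pd.Series(rng.normal(size=n), index=ids, name="t")
        s = ChainSettings(n_iter=4000, burn_in=1000, thin=2, seed=5)
        lam = 0.9
        single = fit_rkhs_ka(y, intercept_design(ids), [K], settings=s, fix_ratios=[lam])
        triple = fit_rkhs_ka(
            y, intercept_design(ids), [K, K, K], settings=s, fix_ratios=[lam / 3] * 3
        )
        np.testing.assert_allclose(predict(triple, ids), predict(single, ids), atol=0.1)

    def test_epistatic_trait_favours_rkhs_over_gblup(self):
        """Pairwise-product epistasis in a structured (family) population:
        the Gaussian-kernel model matches or beats the additive model in most
        replicates, because relatives share interaction genotypes that the
        additive relationship cannot encode."""
        from conftest import tiny_config
        from phenopred.kinship import filter_markers
        from phenopred.simulate import simulate_population

        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = tiny_config(
                seed=seed,
                n_markers=150,
                family_sizes=(10, 10, 10, 10, 10),
                n_both=25,
                n_t1_only=8,
                n_t2_only=8,
                n_blocks=8,
            )
            pop = simulate_population(cfg)
            gm, _ = filter_markers(pop["hybrids"])
            ids = gm.ids
            rng = np.random.default_rng(seed + 500)
            D = gm.dosages - gm.dosages.mean(0)
            C = rng.normal(size=(gm.m, gm.m))
            C = (C + C.T) / 2
            np.fill_diagonal(C, 0)
            g = np.einsum("ij,jk,ik->i", D, C, D)
            g = (g - g.mean()) / g.std()
            y = pd.Series(g + rng.normal(scale=0.3, size=gm.n), index=ids, name="t")
            perm = rng.permutation(gm.n)
            n_train = int(0.8 * gm.n)
            train = [ids[i] for i in perm[:n_train]]
            test = [ids[i] for i in perm[n_train:]]
            gb = fit_blup(y.loc[train], intercept_design(ids), [vanraden_grm(gm)])
            r_gb = np.corrcoef(predict(gb, test), y.loc[test])[0, 1]
            rk = fit_rkhs_ka(
                y.loc[train],
                intercept_design(ids),
                gaussian_kernels(D, ids),
                settings=ChainSettings(n_iter=1000, burn_in=300, thin=3, seed=seed),
            )
            r_rk = np.corrcoef(predict(rk, test), y.loc[test])[0, 1]
            wins += r_rk >= r_gb
        assert wins >= 0.7 * n_seeds

    def test_empty_kernel_list_rejected(self, rng):
        y = pd.Series(rng.normal(size=5), index=list("abcde"), name="t")
        with pytest.raises(ValueError):
            fit_rkhs_ka(y, intercept_design(list("abcde")), [])


class TestMLTuning:
    def test_mtry_upper_bound_is_third_of_columns(self):
        assert MLModelSpec().mtry_bounds(6300) == (100, 2100)
        assert MLModelSpec().mtry_bounds(90) == (30, 30)

    def test_rf_configurations_respect_bounds(self, rng):
        ids = [f"i{k}" for k in range(48)]
        X = pd.DataFrame(rng.normal(size=(48, 30)), index=ids)
        y = pd.Series(X.iloc[:, 0] + rng.normal(scale=0.1, size=48), index=ids, name="t")
        spec = MLModelSpec(learner="random-forest", n_trees=60)
        model = tune_and_fit_ml(y, X, spec, seed=0)
        lo, hi = spec.mtry_bounds(30)
        assert model.trace["mtry"].between(lo, hi).all()
        assert model.trace["min.node.size"].between(3, 15).all()
        assert len(model.trace) == spec.n_initial + spec.n_sequential

    def test_svr_recovers_noiseless_linear_trait(self, rng):
        n = 400
        ids = [f"i{k}" for k in range(n)]
        X = pd.DataFrame(rng.normal(size=(n, 5)), index=ids)
        y = pd.Series(X.to_numpy() @ np.array([1.0, -2.0, 0.5, 3.0, -1.0]), index=ids, name="t")
        spec = MLModelSpec(learner="support-vector-regression")
        model = tune_and_fit_ml(y.iloc[:320], X.iloc[:320], spec, seed=1)
        held = np.asarray(model.estimator.predict(X.iloc[320:].to_numpy()))
        r = np.corrcoef(held, y.iloc[320:])[0, 1]
        assert r > 0.95
        assert model.trace["C"].between(*spec.c_range).all()
        assert model.trace["epsilon"].between(*spec.epsilon_range).all()

    def test_too_few_observations_rejected(self, rng):
        ids = list("abcde")
        X = pd.DataFrame(rng.normal(size=(5, 3)), index=ids)
        y = pd.Series(rng.normal(size=5), index=ids, name="t")
        with pytest.raises(ValueError):
            tune_and_fit_ml(y, X, MLModelSpec(), seed=0)
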