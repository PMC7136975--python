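import numpy as np
import pandas as pd
import pytest

from gradscape.mlpe import (PairStructure, boxcox, dependency_rho, dredge,
                            fit_mlpe, incidence_matrix, moran_permutation_test,
                            r2_nakagawa, residual_autocorrelation, vif_prune)
from gradscape.sites import SiteSet, pair_index
from gradscape.synthetic import MLPESimSpec, simulate_mlpe_response


@pytest.fixture(scope="module")
def sites():
    r = np.random.default_rng(7)
    return SiteSet([f"S{i}" for i in range(17)],
                   r.uniform(0, 1e4, 17), r.uniform(0, 1e4, 17))


class TestBoxCox:
    def test_lognormal_lambda_near_zero(self, rng):
        y = np.exp(rng.normal(size=2000))
        assert -0.15 <= boxcox(y).lam <= 0.15

    def test_normal_lambda_near_one(self, rng):
        y = rng.normal(size=2000) + 10.0
        assert 0.7 <= boxcox(y).lam <= 1.3

    def test_identity_lambda_closed_form(self, rng):
        y = rng.normal(size=100) + 10.0
        res = boxcox(y, lam_grid=np.array([1.0]))
        np.testing.assert_allclose(res.transformed, y + res.shift - 1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            boxcox(np.full(20, 3.0))

    def test_shift_makes_positive(self, rng):
        y = rng.normal(size=100) - 50.0
        res = boxcox(y)
        assert (y + res.shift > 0).all()


class TestVifPrune:
    def test_orthogonal_columns_kept(self):
        X = pd.DataFrame(np.eye(6)[:, :3], columns=list("abc"))
        kept, removed = vif_prune(X)
        assert removed == []
        assert list(kept.columns) == list("abc")

    def test_exact_collinearity_dropped_first(self, rng):
        a, b = rng.normal(size=(2, 50))
        X = pd.DataFrame({"x1": a, "x2": b, "x3": a + b})
        kept, removed = vif_prune(X)
        assert len(removed) == 1 and np.isinf(removed[0][1])
        assert removed[0][0] == "x3"  # ties broken toward the later column

    def test_matches_bruteforce_oracle(self, rng):
        # three correlated Gaussians: replay the greedy removal by hand
        z = rng.normal(size=200)
        X = pd.DataFrame({f"x{k}": z + rng.normal(scale=0.2, size=200)
                          for k in range(3)})

        def oracle_vifs(df):
            out = {}
            for c in df.columns:
                others = df.drop(columns=c)
                A = np.column_stack([np.ones(len(df)), others])
                r = df[c] - A @ np.linalg.lstsq(A, df[c], rcond=None)[0]
                r2 = 1 - (r ** 2).sum() / ((df[c] - df[c].mean()) ** 2).sum()
                out[c] = 1 / (1 - r2)
            return out

        expected_removed = []
        work = X.copy()
        while work.shape[1] >= 2:
            v = oracle_vifs(work)
            worst = max(work.columns[::-1], key=lambda c: v[c])
            if v[worst] < 10:
                break
            expected_removed.append(worst)
            work = work.drop(columns=worst)
        kept, removed = vif_prune(X, threshold=10)
        assert [c for c, _ in removed] == expected_removed
        assert list(kept.columns) == list(work.columns)


class TestFitMlpe:
    def test_incidence_two_loadings_per_row(self, sites):
        Z = incidence_matrix(pair_index(sites), sites)
        assert Z.shape == (136, 17)
        np.testing.assert_array_equal(Z.sum(axis=1), 2.0)
        np.testing.assert_array_equal(Z.sum(axis=0), 16.0)

    def test_zero_sigma_u_reduces_to_ols(self, sites, rng):
        X = rng.normal(size=(136, 2))
        y = 1.0 + X @ [2.0, -1.0] + rng.normal(scale=0.5, size=136)
        fit = fit_mlpe(y, X, sites)
        if fit.sigma_u2 == 0.0:
            ols = np.linalg.lstsq(np.column_stack([np.ones(136), X]), y,
                                  rcond=None)[0]
            np.testing.assert_allclose(fit.beta, ols, atol=1e-8)

    def test_boundary_recovery_when_no_site_effects(self, sites, rng):
        hits = 0
        X = rng.normal(size=(136, 2))
        struct = PairStructure.from_sites(sites)
        for s in range(50):
            y = simulate_mlpe_response(
                X, sites, MLPESimSpec(np.array([0.0, 1.0, 1.0]),
                                      sigma_u=0.0, sigma_e=1.0, seed=s))
            fit = fit_mlpe(y, X, sites, struct=struct)
            if fit.sigma_u2 <= 0.02 * fit.sigma_e2:
                hits += 1
        assert hits >= 45  # >= 90% of replicates at the boundary

    def test_profile_optimum_dominates_perturbations(self, sites, rng):
        from gradscape.mlpe import _profile_crit

        X = rng.normal(size=(136, 2))
        y = simulate_mlpe_response(
            X, sites, MLPESimSpec(np.array([0.0, 1.5, -0.8]), 0.5, 0.5, seed=1))
        struct = PairStructure.from_sites(sites)
        fit = fit_mlpe(y, X, sites, struct=struct)
        Xd = np.column_stack([np.ones(136), X])
        for theta in rng.uniform(0.0, 20.0, 50):
            ll = _profile_crit(theta, y, Xd, struct, reml=False)[0]
            assert fit.loglik >= ll - 1e-8

    def test_parameter_recovery(self, sites, rng):
        X = rng.normal(size=(136, 2))
        struct = PairStructure.from_sites(sites)
        betas = []
        for s in range(60):
            y = simulate_mlpe_response(
                X, sites, MLPESimSpec(np.array([0.0, 1.5, -0.8]), 0.5, 0.5,
                                      seed=1000 + s))
            betas.append(fit_mlpe(y, X, sites, struct=struct).beta)
        mean_beta = np.mean(betas, axis=0)
        np.testing.assert_allclose(mean_beta, [0.0, 1.5, -0.8], atol=0.1)

    def test_row_count_validated(self, sites):
        with pytest.raises(ValueError, match="rows"):
            fit_mlpe(np.zeros(10), None, sites)


class TestDredge:
    def test_orthogonal_predictors_full_enumeration(self, sites, rng):
        X = pd.DataFrame(rng.normal(size=(136, 3)), columns=list("abc"))
        y = rng.normal(size=136)
        table = dredge(y, X, sites)
        assert len(table) == 8  # 2^3 subsets, intercept-only included
        assert table["delta_aic"].iloc[0] == 0.0
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_collinearity_filter_matches_oracle(self, sites, rng):
        import itertools

        a = rng.normal(size=136)
        X = pd.DataFrame({"a": a, "b": a + rng.normal(scale=0.1, size=136),
                          "c": rng.normal(size=136)})
        corr = X.corr().abs().to_numpy()
        expected = sum(
            1 for k in range(4) for sub in itertools.combinations(range(3), k)
            if all(corr[i, j] < 0.6 for i, j in itertools.combinations(sub, 2)))
        y = rng.normal(size=136)
        assert len(dredge(y, X, sites)) == expected
        assert not any({"a", "b"} <= set(p)
                       for p in dredge(y, X, sites)["predictors"])

    def test_aic_sorted(self, sites, rng):
        X = pd.DataFrame(rng.normal(size=(136, 2)), columns=["u", "v"])
        t = dredge(rng.normal(size=136), X, sites)
        assert (np.diff(t["aic"]) >= 0).all()


class TestSummaries:
    def test_intercept_only_marginal_zero(self, sites, rng):
        y = rng.normal(size=136)
        fit = fit_mlpe(y, None, sites, method="REML")
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert r2c >= r2m

    def test_no_site_variance_makes_r2_equal_and_rho_zero(self, sites, rng):
        X = np.asarray(rng.normal(size=(136, 1)))
        y = 2.0 * X[:, 0] + rng.normal(size=136)
        fit = fit_mlpe(y, X, sites, method="REML")
        if fit.sigma_u2 == 0.0:
            r2m, r2c = r2_nakagawa(fit)
            assert r2m == pytest.approx(r2c)
            assert dependency_rho(fit) == 0.0

    def test_rho_closed_form(self, sites):
        fit = fit_mlpe(np.random.default_rng(0).normal(size=136), None, sites)
        fit.sigma_u2, fit.sigma_e2 = 1.0, 1.0
        assert dependency_rho(fit) == pytest.approx(1.0 / 3.0)

    def test_r2_plugin_identity(self, rng):
        # planted var(Xb) = 1, 2 sigma_u^2 = 1, sigma_e^2 = 2
        r = np.random.default_rng(3)
        big = SiteSet([f"T{i}" for i in range(40)],
                      r.uniform(0, 1e4, 40), r.uniform(0, 1e4, 40))
        n = big.n_pairs
        X = r.normal(size=(n, 1))
        struct = PairStructure.from_sites(big)
        vals = []
        for s in range(20):
            y = simulate_mlpe_response(
                X, big, MLPESimSpec(np.array([0.0, 1.0]),
                                    sigma_u=np.sqrt(0.5), sigma_e=np.sqrt(2.0),
                                    seed=s))
            fit = fit_mlpe(y, X, big, method="REML", struct=struct)
            vals.append(r2_nakagawa(fit))
        r2m, r2c = np.mean(vals, axis=0)
        assert r2m == pytest.approx(0.25, abs=0.05)
        assert r2c == pytest.approx(0.5, abs=0.05)

    def test_rho_matches_empirical_shared_site_correlation(self):
        r = np.random.default_rng(5)
        big = SiteSet([f"T{i}" for i in range(30)],
                      r.uniform(0, 1e4, 30), r.uniform(0, 1e4, 30))
        pairs = pair_index(big)
        i1 = pairs.index(("T0", "T1"))
        i2 = pairs.index(("T0", "T2"))
        draws = np.array([
            simulate_mlpe_response(np.zeros((len(pairs), 0)), big,
                                   MLPESimSpec(np.array([0.0]), 1.0, 1.0, seed=s))
            for s in range(400)])
        emp = np.corrcoef(draws[:, i1], draws[:, i2])[0, 1]
        assert emp == pytest.approx(1.0 / 3.0, abs=0.15)


class TestMoran:
    def test_p_value_bounds(self, sites, rng):
        for s in range(5):
            _, p = moran_permutation_test(rng.normal(size=17), sites,
                                          n_perm=999, seed=s)
            assert 1 / 1000 <= p <= 1.0

    def test_smooth_trend_detected(self, sites):
        values = sites.x / sites.x.max()  # strong spatial trend
        _, p = moran_permutation_test(values, sites, seed=0)
        assert p <= 0.05

    def test_residual_autocorrelation_needs_sites(self, rng):
        small = SiteSet(list("abcd"), np.arange(4.0), np.zeros(4))
        y = rng.normal(size=6)
        fit = fit_mlpe(y, None, small)
        with pytest.raises(ValueError, match="5 sites"):
            residual_autocorrelation(fit, small)
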