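import numpy as np
import pandas as pd
import pytest

from orchard.gp_models import (
    MODEL_KERNELS,
    McmcConfig,
    RKHSRegressor,
    build_kernels,
    fit_gibbs,
    predict,
)

from conftest import grm_from_dosages, make_grm


def _records(individuals, collections=None, traits=None):
    n = len(individuals)
    return pd.DataFrame(
        {
            "individual_id": individuals,
            "collection": collections if collections is not None else ["E1"] * n,
            "trait": traits if traits is not None else ["t"] * n,
        }
    )


class TestBuildKernels:
    def test_hand_hadamard_product(self):
        VG = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
        grm = make_grm(VG, ids=np.array(["a", "b", "c"], dtype=object))
        recs = _records(["a", "b", "c"], collections=["A", "A", "B"])
        ks = build_kernels("GxE", recs, grm)
        expected_ge = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        np.testing.assert_allclose(ks.kernels["GE"], expected_ge)
        np.testing.assert_allclose(ks.kernels["G"], VG)

    def test_single_environment_degenerate_kernels(self):
        VG = np.eye(4) * 0.9 + 0.1
        grm = make_grm(VG)
        recs = _records([f"ind{i:04d}" for i in range(4)])
        with pytest.raises(ValueError, match="environments"):
            build_kernels("GxE", recs, grm)
        ks = build_kernels("GxE", recs, grm, strict=False)
        np.testing.assert_allclose(ks.kernels["E"], np.ones((4, 4)))
        np.testing.assert_allclose(ks.kernels["GE"], ks.kernels["G"])

    def test_disjoint_environments_zero_cross_blocks(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((6, 12))
        grm = make_grm(A @ A.T / 12)
        env = ["X", "X", "X", "Y", "Y", "Y"]
        recs = _records([f"ind{i:04d}" for i in range(6)], collections=env)
        ks = build_kernels("GxE", recs, grm)
        ge = ks.kernels["GE"]
        assert np.all(ge[:3, 3:] == 0)
        assert np.all(ge[3:, :3] == 0)

    def test_model_kernel_membership(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((8, 20))
        grm = make_grm(A @ A.T / 20)
        recs = _records(
            [f"ind{i:04d}" for i in range(4)] * 2,
            collections=["X"] * 4 + ["Y"] * 4,
            traits=["t1"] * 4 + ["t2"] * 4,
        )
        # records reuse four individuals over two collections/traits
        recs["individual_id"] = [f"ind{i:04d}" for i in range(4)] * 2
        for model, names in MODEL_KERNELS.items():
            ks = build_kernels(model, recs, grm)
            assert tuple(ks.kernels) == names

    def test_unknown_model_and_missing_individual(self):
        grm = make_grm(np.eye(3))
        recs = _records(["ind0000", "ind0001", "ind0002"])
        with pytest.raises(ValueError, match="unknown model"):
            build_kernels("BayesB", recs, grm)
        bad = _records(["nope", "ind0001", "ind0002"])
        with pytest.raises(KeyError):
            build_kernels("Single", bad, grm)


class TestGibbs:
    def _toy(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((n, 30))
        K = A @ A.T / 30
        grm = make_grm(K)
        recs = _records([f"ind{i:04d}" for i in range(n)])
        return build_kernels("Single", recs, grm), K

    def test_pinned_variances_match_blup(self):
        # near-degenerate priors pin the variance components; posterior-mean
        # effects must then equal the closed-form BLUP solution
        ks, K = self._toy(seed=3)
        y = np.array([1.0, 2.0, 0.5, -1.0, 0.0, 1.5])
        est = RKHSRegressor(
            n_burn_in=2000, n_sampling=40_000, thin=1,
            prior_df=1e8, prior_r2=0.5, seed=5,
        ).fit(ks, y)
        sg, se = est.varcomp_["G"][0], est.varcomp_["eps"][0]
        V = sg * K + se * np.eye(6)
        Vi = np.linalg.inv(V)
        one = np.ones(6)
        mu = (one @ Vi @ y) / (one @ Vi @ one)
        blup = sg * K @ Vi @ (y - mu * one)
        assert np.abs(blup - est.effects_["G"]).max() < 0.01

    def test_deterministic_under_seed(self):
        ks, _ = self._toy(seed=1)
        y = np.arange(6.0)
        a = RKHSRegressor(n_burn_in=50, n_sampling=100, thin=1, seed=9).fit(ks, y)
        b = RKHSRegressor(n_burn_in=50, n_sampling=100, thin=1, seed=9).fit(ks, y)
        np.testing.assert_array_equal(a.gebv_, b.gebv_)
        assert a.varcomp_ == b.varcomp_

    def test_all_missing_rejected(self):
        ks, _ = self._toy()
        with pytest.raises(ValueError, match="missing"):
            RKHSRegressor(n_burn_in=10, n_sampling=10).fit(ks, np.full(6, np.nan))

    def test_non_psd_kernel_named(self):
        grm = make_grm(np.eye(3))
        recs = _records(["ind0000", "ind0001", "ind0002"])
        ks = build_kernels("Single", recs, grm)
        ks.kernels["G"] = np.array(
            [[1.0, 0.99, 0.0], [0.99, 1.0, -0.99], [0.0, -0.99, -1.0]]
        )
        with pytest.raises(ValueError, match="G"):
            RKHSRegressor(n_burn_in=10, n_sampling=10).fit(ks, np.arange(3.0))

    def test_null_phenotype_posterior_matches_integration_oracle(self):
        # pure-noise phenotype: the Gibbs posterior mean of sigma2_G must
        # agree with direct 2-D numerical integration of the variance
        # posterior (intercept integrated out under its flat prior), and the
        # GEBVs must not correlate with anything
        rng = np.random.default_rng(4)
        n, m = 300, 150
        X = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        K = grm_from_dosages(X)
        grm = make_grm(K)
        recs = _records([f"ind{i:04d}" for i in range(n)])
        ks = build_kernels("Single", recs, grm)
        y = np.random.default_rng(101).standard_normal(n)

        S, U = np.linalg.eigh(K)
        S = np.clip(S, 0, None)
        yr, xr = U.T @ y, U.T @ np.ones(n)
        vy = y.var()
        df0 = 5.0
        s0 = vy * 0.5 * (df0 + 2) / df0  # prior scale, mode = vy*R2/K

        def log_post(sg, se):
            v = S * sg + se
            wi = 1.0 / v
            xwx = np.sum(xr * wi * xr)
            beta = np.sum(xr * wi * yr) / xwx
            r = yr - xr * beta
            ll = -0.5 * (np.sum(np.log(v)) + np.log(xwx) + np.sum(r * wi * r))
            lp = sum(
                -(df0 / 2 + 1) * np.log(s) - df0 * s0 / (2 * s) for s in (sg, se)
            )
            return ll + lp

        gs = np.linspace(0.001, 1.5, 100) * vy
        es = np.linspace(0.05, 2.0, 100) * vy
        L = np.array([[log_post(a, b) for b in es] for a in gs])
        P = np.exp(L - L.max())
        oracle_mean = np.sum(P.sum(axis=1) * gs) / P.sum()

        est = RKHSRegressor(
            n_burn_in=2000, n_sampling=6000, thin=2, prior_df=5.0, seed=1
        ).fit(ks, y)
        assert abs(est.varcomp_["G"][0] - oracle_mean) < 0.02 * vy
        probe = np.random.default_rng(200).standard_normal(n)
        assert abs(np.corrcoef(est.gebv_, probe)[0, 1]) < 0.15

    def test_high_h2_recovery_on_masked_records(self):
        # n well above the marker count, so masked individuals are densely
        # connected to the training set through the kernel
        rng = np.random.default_rng(6)
        X = rng.binomial(2, rng.uniform(0.2, 0.8, 120), size=(300, 120)).astype(float)
        K = grm_from_dosages(X)
        g = (X - X.mean(0)) @ rng.standard_normal(120)
        g = g / g.std()
        y = g + 0.1 * rng.standard_normal(300)  # h2 ~ 0.99
        grm = make_grm(K)
        recs = _records([f"ind{i:04d}" for i in range(300)])
        ks = build_kernels("Single", recs, grm)
        masked = rng.choice(300, 60, replace=False)
        y_obs = y.copy()
        y_obs[masked] = np.nan
        fit = fit_gibbs(y_obs, ks, McmcConfig(500, 1500, 2, seed=1))
        gebv = predict(fit, masked)
        assert np.corrcoef(gebv, g[masked])[0, 1] > 0.8

    def test_clone_record_consistency(self):
        rng = np.random.default_rng(7)
        X = rng.binomial(2, rng.uniform(0.2, 0.8, 400), size=(80, 400)).astype(float)
        X[1] = X[0]  # clone pair
        K = grm_from_dosages(X)
        g = (X - X.mean(0)) @ rng.standard_normal(400)
        g = g / g.std()
        y = g + 0.1 * rng.standard_normal(80)
        grm = make_grm(K)
        recs = _records([f"ind{i:04d}" for i in range(80)])
        ks = build_kernels("Single", recs, grm)
        y_obs = y.copy()
        y_obs[1] = np.nan  # mask one clone, observe the other
        est = RKHSRegressor(n_burn_in=500, n_sampling=1500, thin=2, seed=2).fit(
            ks, y_obs
        )
        assert abs(est.gebv_[1] - est.gebv_[0]) < 0.1 * est.gebv_.std()

    def test_predict_unknown_record_rejected(self):
        ks, _ = self._toy()
        est = RKHSRegressor(n_burn_in=20, n_sampling=20).fit(ks, np.arange(6.0))
        with pytest.raises(IndexError):
            est.predict([17])
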