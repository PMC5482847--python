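"""Mediation regressions and the exclusion mask."""

import numpy as np
import pytest

from dyadsync.mediation import (MODELS, MediationScan, exclusion_mask,
                                fit_mediation, mediation_scan)


class TestFitMediation:
    def test_perfect_fit_gives_unit_r2(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=30)
        fit = fit_mediation(x1, x1, rng.normal(size=30), "listener_only")
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.p == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_ols_oracle(self):
        """Closed-form OLS equals the statsmodels fit to 1e-8."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(size=30), rng.normal(size=30)
        y = 0.3 + 0.5 * x1 - 0.2 * x2 + 0.1 * x1 * x2 + 0.05 * rng.normal(size=30)
        for model, cols in (("full", [x1, x2, x1 * x2]),
                            ("listener_only", [x1]), ("speaker_only", [x2])):
            fit = fit_mediation(y, x1, x2, model)
            X = sm.add_constant(np.column_stack(cols))
            ref = sm.OLS(y, X).fit()
            assert np.allclose(fit.beta, ref.params, atol=1e-8)
            assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-8)
            assert fit.F == pytest.approx(ref.fvalue, rel=1e-8)
            assert fit.p == pytest.approx(ref.f_pvalue, abs=1e-10)
            assert fit.df == (ref.df_model, ref.df_resid)

    def test_known_coefficients_recovered_within_3_se(self):
        rng = np.random.default_rng(2)
        beta = np.array([0.1, 0.5, -0.3, 0.2])
        x1, x2 = rng.normal(size=30), rng.normal(size=30)
        X = np.column_stack([np.ones(30), x1, x2, x1 * x2])
        y = X @ beta + 0.01 * rng.normal(size=30)
        fit = fit_mediation(y, x1, x2, "full")
        # closed-form OLS standard errors via the normal equations
        resid = y - X @ fit.beta
        sigma2 = resid @ resid / (30 - 4)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(fit.beta - beta) < 3 * se)

    def test_null_r2_distribution_mean(self):
        """Under independence, E[R^2] ~ k/(n-1) for k predictors at n=30."""
        rng = np.random.default_rng(3)
        n, reps = 30, 300
        r2_full, r2_part, pvals = [], [], []
        for _ in range(reps):
            y = rng.normal(size=n)
            x1, x2 = rng.normal(size=n), rng.normal(size=n)
            f = fit_mediation(y, x1, x2, "full")
            r2_full.append(f.r2)
            pvals.append(f.p)
            r2_part.append(fit_mediation(y, x1, x2, "listener_only").r2)
        assert np.mean(r2_full) == pytest.approx(3 / (n - 1), abs=0.03)
        assert np.mean(r2_part) == pytest.approx(1 / (n - 1), abs=0.02)
        # p uniform: rejection rate at 0.05 within binomial error
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_degenerate_predictors_flagged(self):
        y = np.random.default_rng(4).normal(size=30)
        fit = fit_mediation(y, np.ones(30), np.ones(30), "full")
        assert not fit.ok and np.isnan(fit.p)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_mediation(np.zeros(4), np.zeros(4), np.zeros(4), "full")

    def test_non_finite_rejected(self):
        y = np.zeros(30)
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_mediation(y, np.ones(30), np.ones(30), "full")


class TestScan:
    def _world(self, n=30, L=3, S=3, B=2, seed=5, mediated=None):
        rng = np.random.default_rng(seed)
        env_l = rng.normal(size=(n, L, B))
        env_s = rng.normal(size=(n, S, B))
        bb = 0.1 * rng.normal(size=(n, L, S, B))
        for (l, s, b) in mediated or []:
            bb[:, l, s, b] += 0.8 * env_l[:, l, b] + 0.8 * env_s[:, s, b]
        return bb, env_l, env_s

    def test_fit_count_and_nesting(self):
        bb, env_l, env_s = self._world()
        scan = mediation_scan(bb, env_l, env_s, ["delta", "theta"])
        for m in MODELS:
            assert scan.r2[m].shape == (3, 3, 2)
        assert np.all(scan.r2["full"] >= scan.r2["listener_only"] - 1e-12)
        assert np.all(scan.r2["full"] >= scan.r2["speaker_only"] - 1e-12)

    def test_scan_agrees_with_single_fits(self):
        bb, env_l, env_s = self._world()
        scan = mediation_scan(bb, env_l, env_s, ["delta", "theta"])
        f = fit_mediation(bb[:, 1, 2, 0], env_l[:, 1, 0], env_s[:, 2, 0], "full")
        assert scan.r2["full"][1, 2, 0] == pytest.approx(f.r2, abs=1e-12)
        assert scan.p["full"][1, 2, 0] == pytest.approx(f.p, abs=1e-12)

    def test_mediated_cells_detected_null_cells_at_chance(self):
        hits, false = [], []
        for seed in range(20):
            bb, env_l, env_s = self._world(seed=seed, mediated=[(0, 0, 0)])
            scan = mediation_scan(bb, env_l, env_s, ["delta", "theta"])
            sig = scan.significant("full")
            hits.append(sig[0, 0, 0])
            false.append(np.delete(sig.ravel(), 0).mean())
        assert np.mean(hits) >= 0.9
        assert np.mean(false) < 0.12

    def test_dimension_mismatch_rejected(self):
        bb, env_l, env_s = self._world()
        with pytest.raises(ValueError):
            mediation_scan(bb, env_l[:, :2], env_s, ["delta", "theta"])


class TestExclusionMask:
    def _scan_with_p(self, p_any, bands):
        L, S, B = p_any.shape
        p = {m: np.ones((L, S, B)) for m in MODELS}
        p["full"] = np.where(p_any, 0.01, 0.5)
        r2 = {m: np.zeros((L, S, B)) for m in MODELS}
        return MediationScan(r2, r2, p, bands)

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(6)
        L = S = 3
        bands = ["alpha"]
        bb_sig = rng.random((L, S, 1)) < 0.5
        med = rng.random((L, S, 1)) < 0.3
        env_l = rng.random((L, 1)) < 0.3
        env_s = rng.random((S, 1)) < 0.3
        mask = exclusion_mask(bb_sig, self._scan_with_p(med, bands), env_l, env_s)
        # brute-force set arithmetic
        expect = {(l, s) for l in range(L) for s in range(S)
                  if bb_sig[l, s, 0] and not med[l, s, 0]
                  and not env_l[l, 0] and not env_s[s, 0]}
        assert mask.pairs("alpha") == expect
        assert np.all(~mask.surviving | bb_sig)  # surviving subset of bb_sig

    def test_band_with_all_channels_entrained_empties(self):
        bb_sig = np.ones((3, 3, 1), bool)
        med = np.zeros((3, 3, 1), bool)
        env_all = np.ones((3, 1), bool)
        mask = exclusion_mask(bb_sig, self._scan_with_p(med, ["delta"]),
                              env_all, env_all)
        assert mask.pairs("delta") == set()

    def test_nothing_to_remove_keeps_bb_sig(self):
        rng = np.random.default_rng(7)
        bb_sig = rng.random((4, 4, 2)) < 0.4
        med = np.zeros((4, 4, 2), bool)
        none_l = np.zeros((4, 2), bool)
        mask = exclusion_mask(bb_sig, self._scan_with_p(med, ["a", "b"]),
                              none_l, none_l)
        assert np.array_equal(mask.surviving, bb_sig)
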