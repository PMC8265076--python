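import numpy as np
import pytest

from itseg import (
    CandidateSet,
    ITSDataset,
    NoiseParams,
    changepoint_profile,
    conditional_loglik,
    design_matrix,
    fit_its_model,
    gls_fit,
    irls_unit_fit,
    level_change,
    mom_noise,
    simulate_dataset,
    whitening_weights,
)
from itseg.estimation import DegenerateDataError

from conftest import make_spec


class TestGLS:
    def test_identity_weights_reduce_to_ols(self, rng):
        n = 40
        X = design_matrix(n, 17)
        y = rng.normal(size=n)
        coef, cov = gls_fit(y, X, np.eye(n))
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.max(np.abs(coef - ols)) < 1e-10
        assert np.max(np.abs(cov - np.linalg.inv(X.T @ X))) < 1e-10

    def test_recovers_exact_signal_under_any_weights(self, rng):
        n = 30
        X = design_matrix(n, 12)
        beta = np.array([2.0, -0.3, 1.5, 0.2])
        L = whitening_weights(NoiseParams("ar1", 0.5, -0.3, 0.8, 1.2), n, 12)
        coef, _ = gls_fit(X @ beta, X, L)
        assert np.max(np.abs(coef - beta)) < 1e-9

    def test_matches_dense_normal_equations(self, rng):
        # oracle: explicit (X' S^-1 X)^-1 X' S^-1 y with S^-1 = L'L
        n = 25
        X = design_matrix(n, 11)
        y = rng.normal(size=n)
        L = whitening_weights(NoiseParams("ar1", 0.6, 0.2, 1.0, 0.5), n, 11).matrix()
        Sinv = L.T @ L
        oracle = np.linalg.inv(X.T @ Sinv @ X) @ X.T @ Sinv @ y
        coef, cov = gls_fit(y, X, L)
        assert np.max(np.abs(coef - oracle)) < 1e-10
        assert np.max(np.abs(cov - np.linalg.inv(X.T @ Sinv @ X))) < 1e-10

    def test_rank_deficiency_raises(self, rng):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(np.linalg.LinAlgError):
            gls_fit(rng.normal(size=10), X, np.eye(10))


class TestMomNoise:
    def test_iid_residuals_give_small_phi(self, rng):
        r = np.random.default_rng(7).normal(size=2000)
        noise = mom_noise(r, 1000, "ar1")
        assert -0.1 < noise.phi1 < 0.1
        assert -0.1 < noise.phi2 < 0.1
        # innovation variance identity: phase variance times (1 - phi^2)
        z = r[:999] - r[:999].mean()
        s2 = z @ z / (len(z) - 2)
        assert noise.sigma2_w1 == pytest.approx(s2 * (1 - noise.phi1**2), rel=1e-12)

    def test_recovers_ar1_phi(self):
        g = np.random.default_rng(11)
        n = 8000
        r = np.empty(n)
        r[0] = g.normal()
        for t in range(1, n):
            r[t] = 0.7 * r[t - 1] + g.normal()
        noise = mom_noise(r, n // 2 + 1, "ar1")
        assert 0.65 <= noise.phi1 <= 0.75
        assert 0.65 <= noise.phi2 <= 0.75

    def test_constant_residuals_are_degenerate(self):
        with pytest.raises(DegenerateDataError):
            mom_noise(np.ones(40), 20, "ar1")

    def test_too_short_phase_raises(self):
        with pytest.raises(DegenerateDataError):
            mom_noise(np.random.default_rng(0).normal(size=10), 3, "ar1")

    def test_independent_structure_zero_phi(self, rng):
        noise = mom_noise(rng.normal(size=100), 50, "independent")
        assert noise.phi1 == 0.0 and noise.phi2 == 0.0


class TestConditionalLoglik:
    def test_standard_normal_at_zero_residuals(self):
        noise = NoiseParams("ar1", 0.0, 0.0, 1.0, 1.0)
        ll = conditional_loglik(np.zeros(11), noise, 6)
        assert ll == pytest.approx(-(10 / 2) * np.log(2 * np.pi), abs=1e-12)

    def test_matches_scalar_density_loop(self, rng):
        from scipy import stats

        n, tau = 23, 9
        r = rng.normal(size=n)
        noise = NoiseParams("ar1", 0.4, -0.3, 1.3, 0.6)
        expected = 0.0
        for t in range(2, n + 1):
            phi, s2 = (0.4, 1.3) if t <= tau - 1 else (-0.3, 0.6)
            e = r[t - 1] - phi * r[t - 2]
            expected += stats.norm.logpdf(e, scale=np.sqrt(s2))
        assert conditional_loglik(r, noise, tau) == pytest.approx(expected, abs=1e-12)

    def test_first_marginal_term_toggle(self, rng):
        from scipy import stats

        r = rng.normal(size=15)
        noise = NoiseParams("ar1", 0.5, 0.5, 1.0, 1.0)
        base = conditional_loglik(r, noise, 8)
        full = conditional_loglik(r, noise, 8, include_first_marginal=True)
        extra = stats.norm.logpdf(r[0], scale=np.sqrt(1 / (1 - 0.25)))
        assert full - base == pytest.approx(extra, abs=1e-12)

    def test_variance_profile_peaks_at_optimum(self, rng):
        r = rng.normal(size=200)
        best_s2 = float(np.mean((r[1:]) ** 2))  # phi=0 optimum of the conditional ll
        lls = [
            conditional_loglik(r, NoiseParams("ar1", 0.0, 0.0, s2, s2), 100)
            for s2 in (best_s2 * 0.5, best_s2, best_s2 * 2.0, best_s2 * 4.0)
        ]
        assert lls[1] == max(lls)
        assert lls[2] > lls[3]  # moving further away keeps decreasing


class TestIRLS:
    def test_independent_equals_segmented_ols(self):
        spec = make_spec(structure="independent", delta=2.0, seed=3)
        u = simulate_dataset(spec).units[0]
        fit = irls_unit_fit(u, 50, "independent")
        X = design_matrix(u.n, 50)
        ols = np.linalg.solve(X.T @ X, X.T @ u.values)
        assert np.max(np.abs(fit.mean.as_array() - ols)) < 1e-8

    def test_deterministic(self):
        spec = make_spec(delta=1.0, seed=9)
        u = simulate_dataset(spec).units[0]
        f1 = irls_unit_fit(u, 50, "ar1")
        f2 = irls_unit_fit(u, 50, "ar1")
        assert np.array_equal(f1.mean.as_array(), f2.mean.as_array())
        assert f1.noise == f2.noise
        assert f1.loglik == f2.loglik

    def test_residuals_plus_fitted_reconstruct_values(self, ar1_dataset):
        ds, _ = ar1_dataset
        fit = irls_unit_fit(ds.units[0], 50, "ar1")
        assert np.allclose(fit.residuals + fit.fitted, ds.units[0].values)

    def test_parameter_recovery_within_three_se(self):
        spec = make_spec(
            n=500, tau=250, delta=2.0, Delta=0.01, phi1=0.4, phi2=0.6, s2_2=0.8, seed=21
        )
        u = simulate_dataset(spec).units[0]
        fit = irls_unit_fit(u, 250, "ar1")
        est = fit.mean.as_array()
        truth = np.array([10.0, 0.05, 2.0, 0.01])
        se = np.sqrt(np.diag(fit.mean_cov))
        assert np.all(np.abs(est - truth) < 3 * se)
        assert abs(fit.noise.phi1 - 0.4) < 3 * np.sqrt((1 - 0.16) / 249)
        assert abs(fit.noise.phi2 - 0.6) < 3 * np.sqrt((1 - 0.36) / 251)

    def test_exchangeable_structure_fits(self, ar1_dataset):
        ds, _ = ar1_dataset
        fit = irls_unit_fit(ds.units[0], 50, "exchangeable")
        assert np.isfinite(fit.loglik)
        assert fit.noise.structure == "exchangeable"


class TestProfileAndFit:
    def test_strong_level_jump_recovers_tau(self):
        cands = CandidateSet(np.arange(40, 61))
        hits = 0
        for seed in range(10):
            sd = np.sqrt(1 / (1 - 0.09))
            spec = make_spec(n=100, tau=50, delta=10 * sd, seed=500 + seed)
            ds = simulate_dataset(spec)
            prof = changepoint_profile(ds, cands, "ar1")
            hits += prof.argmax_index == 50
        assert hits == 10

    def test_profile_argmax_attains_maximum(self, ar1_dataset):
        ds, _ = ar1_dataset
        cands = CandidateSet(np.arange(45, 56))
        prof = changepoint_profile(ds, cands, "ar1")
        best = prof.logliks[prof.valid].max()
        k = list(cands).index(prof.argmax_index)
        assert prof.logliks[k] == best

    def test_level_change_identity(self, ar1_dataset):
        ds, _ = ar1_dataset
        fit = fit_its_model(ds, CandidateSet(np.arange(45, 56)))
        for uf in fit.unit_fits:
            row = fit.summaries.query("unit == @uf.unit_id and quantity == 'level_change'")
            assert row["estimate"].iloc[0] == level_change(uf.mean, fit.tau_hat)
            trend = fit.summaries.query("unit == @uf.unit_id and quantity == 'trend_change'")
            assert trend["estimate"].iloc[0] == uf.mean.Delta

    def test_single_unit_panel_matches_lone_series(self, ar1_dataset):
        ds, _ = ar1_dataset
        lone = ITSDataset(units=ds.units[:1])
        cands = CandidateSet(np.arange(45, 56))
        f_panel = fit_its_model(lone, cands)
        f_unit = irls_unit_fit(ds.units[0], f_panel.tau_hat, "ar1")
        assert np.array_equal(f_panel.unit_fits[0].mean.as_array(), f_unit.mean.as_array())

    def test_level_change_ci_coverage_at_fixed_tau(self):
        # null data, single fixed candidate: the 95% Wald CI for the level
        # change should cover 0 at roughly the nominal rate
        cands = CandidateSet(np.array([50]))
        cover = 0
        reps = 200
        for seed in range(reps):
            ds = simulate_dataset(make_spec(seed=3000 + seed))
            fit = fit_its_model(ds, cands)
            row = fit.summaries.query("quantity == 'level_change'").iloc[0]
            cover += row["ci_low"] <= 0 <= row["ci_high"]
        assert 0.90 <= cover / reps <= 0.99
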