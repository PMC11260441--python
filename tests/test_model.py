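"""Gibbs-sampled animal model: conjugate limits, posterior summaries,
diagnostics, DIC arithmetic, and invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedvar.model import (AnimalModelError, ChainSettings, ModelSpec,
                          chain_diagnostics, compute_dic, fit_animal_model,
                          hpd_interval, posterior_mode,
                          prior_sensitivity_scan)
from pedvar.pedigree import validate_pedigree

from conftest import offspring_rows


def unrelated_table(n, seed, mu=0.33, sd=0.03):
    rng = np.random.default_rng(seed)
    ids = [f"I{i}" for i in range(n)]
    ped = validate_pedigree([(i, "", "") for i in ids])
    return ped, pd.DataFrame({"id": ids, "rbw": rng.normal(mu, sd, n)})


class TestConjugateLimit:
    def test_residual_posterior_matches_closed_form(self):
        """Intercept-only model: the marginal posterior of the residual
        variance is scaled-inv-chi2 with nu + n - 1 df and scale built from
        the centered sum of squares (the intercept is integrated out under
        its flat prior).  KS distance of 10^4 Gibbs draws vs the analytic
        CDF is well under 0.05."""
        n = 50
        ped, tbl = unrelated_table(n, seed=42)
        y = tbl["rbw"].to_numpy()
        spec = ModelSpec(random=())
        cs = ChainSettings(n_iterations=11_000, burn_in=1_000, thin=1, seed=7)
        draws = fit_animal_model(tbl, ped, spec, cs).variance_draws["residual"]
        V, nu = spec.prior_for("residual")
        df = nu + n - 1
        ss = nu * V + ((y - y.mean()) ** 2).sum()
        ks = stats.kstest(draws, lambda x: stats.chi2.sf(ss / np.asarray(x),
                                                         df)).statistic
        assert ks < 0.05


class TestPosteriorSummaries:
    def test_mode_of_constant_sample(self):
        assert posterior_mode(np.full(500, 3.25)) == 3.25

    def test_mode_of_normal_sample(self):
        """Mode of 10^5 N(5, 1) draws lands within +-0.05 of 5 (averaged
        over a few seeds to keep the Monte-Carlo check stable)."""
        modes = [posterior_mode(np.random.default_rng(s).normal(5, 1, 100_000))
                 for s in range(5)]
        assert np.mean(modes) == pytest.approx(5.0, abs=0.05)

    def test_mode_of_skewed_sample_below_mean(self):
        rng = np.random.default_rng(1)
        draws = rng.gamma(2.0, 2.0, 100_000)
        assert posterior_mode(draws) < draws.mean()

    def test_mode_rejects_empty(self):
        with pytest.raises(AnimalModelError):
            posterior_mode(np.array([]))

    def test_hpd_uniform_grid(self):
        grid = np.linspace(0.0, 1.0, 2001)
        lo, hi = hpd_interval(grid, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.002)

    def test_hpd_constant_sample(self):
        lo, hi = hpd_interval(np.full(200, 1.5))
        assert lo == hi == 1.5

    def test_hpd_normal_endpoints(self):
        rng = np.random.default_rng(2)
        lo, hi = hpd_interval(rng.normal(0, 1, 100_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_hpd_contains_mass_and_validates_prob(self):
        rng = np.random.default_rng(3)
        draws = rng.exponential(1.0, 5000)
        lo, hi = hpd_interval(draws, 0.9)
        assert ((draws >= lo) & (draws <= hi)).mean() >= 0.9
        with pytest.raises(AnimalModelError):
            hpd_interval(draws, 1.5)


class TestChainDiagnostics:
    def test_iid_chain_ess_near_n(self):
        rng = np.random.default_rng(4)
        n = 10_000
        ess, lag1 = chain_diagnostics(rng.normal(size=n))
        assert 0.8 * n <= ess <= n
        assert abs(lag1) < 0.05

    def test_ar1_chain_ess_closed_form(self):
        rng = np.random.default_rng(5)
        n, rho = 100_000, 0.9
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        ess, lag1 = chain_diagnostics(x)
        expect = n * (1 - rho) / (1 + rho)
        assert ess == pytest.approx(expect, rel=0.2)
        assert lag1 == pytest.approx(rho, abs=0.02)

    def test_constant_chain_convention(self):
        ess, lag1 = chain_diagnostics(np.full(500, 2.0))
        assert ess == 500 and lag1 == 0.0

    def test_agrees_with_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(6)
        n, rho = 20_000, 0.6
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        ess, _ = chain_diagnostics(x)
        ref = float(arviz.ess(x[None, :]))
        assert ess == pytest.approx(ref, rel=0.2)


class TestDIC:
    def test_matches_hand_computation(self):
        rng = np.random.default_rng(7)
        n = 20
        y = rng.normal(0.0, 1.0, n)
        fitted = np.vstack([y * 0.5, y * 0.8])
        s2e = np.array([0.7, 1.3])
        devs = []
        for f, s2 in zip(fitted, s2e):
            devs.append(-2 * stats.norm.logpdf(y, f, math.sqrt(s2)).sum())
        dbar = np.mean(devs)
        dhat = -2 * stats.norm.logpdf(y, fitted.mean(axis=0),
                                      math.sqrt(s2e.mean())).sum()
        expect = 2 * dbar - dhat
        got = compute_dic(y, fitted, s2e, min_draws=2)
        assert got == pytest.approx(expect, abs=1e-9)

    def test_too_few_draws_rejected(self):
        y = np.zeros(5)
        with pytest.raises(AnimalModelError, match="at least"):
            compute_dic(y, np.zeros((10, 5)), np.ones(10))

    def test_degenerate_perfect_fit_guard(self):
        y = np.arange(5.0)
        fitted = np.tile(y, (200, 1))
        with pytest.raises(AnimalModelError):
            compute_dic(y, fitted, np.zeros(200))


class TestFitInvariances:
    SPEC = ModelSpec(random=("animal", "dam", "brood"))
    CHAIN = ChainSettings(n_iterations=2_500, burn_in=500, thin=10, seed=11)

    def test_seed_determinism(self, study):
        ped, _, tbl, _ = study
        off = offspring_rows(tbl)
        a = fit_animal_model(off, ped, self.SPEC, self.CHAIN)
        b = fit_animal_model(off, ped, self.SPEC, self.CHAIN)
        for k in a.variance_draws:
            np.testing.assert_array_equal(a.variance_draws[k],
                                          b.variance_draws[k])

    def test_ratio_normalization(self, study):
        ped, _, tbl, _ = study
        off = offspring_rows(tbl)
        s = fit_animal_model(off, ped, self.SPEC, self.CHAIN)
        total = sum(s.ratio_draws.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_location_shift_leaves_variances_unchanged(self, study):
        """Adding a constant to the trait is absorbed by the intercept; the
        variance draws are unchanged up to solver round-off."""
        ped, _, tbl, _ = study
        off = offspring_rows(tbl)
        shifted = off.assign(rbw=off["rbw"] + 0.125)
        a = fit_animal_model(off, ped, self.SPEC, self.CHAIN)
        b = fit_animal_model(shifted, ped, self.SPEC, self.CHAIN)
        for k in a.variance_draws:
            np.testing.assert_allclose(a.variance_draws[k],
                                       b.variance_draws[k], rtol=1e-7)

    def test_scale_equivariance(self, study):
        """Multiplying the trait by c (and the prior scale by c^2, keeping
        the prior in trait units) multiplies every variance draw by c^2 and
        leaves the ratios bit-identical; c = 4 keeps the arithmetic exact in
        binary floating point."""
        ped, _, tbl, _ = study
        off = offspring_rows(tbl)
        c = 4.0
        scaled_spec = ModelSpec(random=self.SPEC.random,
                                default_prior=(c * c * 1.0, 0.002))
        a = fit_animal_model(off, ped, self.SPEC, self.CHAIN)
        b = fit_animal_model(off.assign(rbw=off["rbw"] * c), ped,
                             scaled_spec, self.CHAIN)
        for k in a.variance_draws:
            np.testing.assert_array_equal(a.variance_draws[k] * c * c,
                                          b.variance_draws[k])
            np.testing.assert_array_equal(a.ratio_draws[k], b.ratio_draws[k])

    def test_rank_deficient_fixed_design_reports_aliased(self, study):
        ped, _, tbl, _ = study
        off = offspring_rows(tbl)
        off = off.assign(condition=off["sex"])  # perfectly collinear
        with pytest.raises(AnimalModelError, match="aliased"):
            fit_animal_model(off, ped, ModelSpec(random=("animal",),
                                                 fixed=("sex", "condition")),
                             self.CHAIN)

    def test_settings_validation(self):
        with pytest.raises(AnimalModelError):
            ChainSettings(n_iterations=100, burn_in=200)
        with pytest.raises(AnimalModelError):
            ChainSettings(n_iterations=300, burn_in=250, thin=10)  # 5 kept
        with pytest.raises(AnimalModelError):
            ModelSpec(random=("animal", "animal"))
        with pytest.raises(AnimalModelError):
            ModelSpec(random=("herd",))
        with pytest.raises(AnimalModelError):
            ModelSpec(default_prior=(0.0, 0.002))


class TestPriorSensitivity:
    def test_single_point_grid_equals_direct_fit(self, study):
        ped, _, tbl, _ = study
        off = offspring_rows(tbl)
        chain = ChainSettings(n_iterations=2_500, burn_in=500, thin=10, seed=3)
        spec = ModelSpec(random=("animal", "dam"))
        scan = prior_sensitivity_scan(off, ped, spec, [0.002], chain)
        direct = fit_animal_model(off, ped, spec.with_nu(0.002), chain)
        np.testing.assert_array_equal(scan[0.002].variance_draws["animal"],
                                      direct.variance_draws["animal"])

    def test_grid_validation(self, study):
        ped, _, tbl, _ = study
        off = offspring_rows(tbl)
        with pytest.raises(AnimalModelError):
            prior_sensitivity_scan(off, ped, ModelSpec(), [0.01, 0.001],
                                   ChainSettings(2500, 500, 10, 0))
        with pytest.raises(AnimalModelError):
            prior_sensitivity_scan(off, ped, ModelSpec(), [-0.1, 0.01],
                                   ChainSettings(2500, 500, 10, 0))

    def test_dam_brood_estimates_grow_with_nu(self, study_additive_only):
        """On additive-only data, stronger priors (larger nu) pull the dam
        and brood variance-ratio estimates upward, while the additive
        estimate stays comparatively stable except at the largest nu."""
        ped, _, tbl, _ = study_additive_only
        off = offspring_rows(tbl)
        chain = ChainSettings(n_iterations=8_000, burn_in=1_000, thin=7,
                              seed=19)
        grid = [0.0005, 0.002, 0.02, 0.05]
        scan = prior_sensitivity_scan(off, ped,
                                      ModelSpec(random=("animal", "dam",
                                                        "brood")),
                                      grid, chain)
        nuisance = [scan[nu].modes["dam"] + scan[nu].modes["brood"]
                    for nu in grid]
        assert nuisance[-1] > nuisance[0]
        additive = [scan[nu].modes["animal"] for nu in grid]
        assert max(additive[:-1]) - min(additive[:-1]) < 0.15
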