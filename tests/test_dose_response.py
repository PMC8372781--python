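"""Likelihoods, MLE fits, closed-form BMDs and profile BMDLs."""

import math

import numpy as np
import pytest
from scipy import optimize, special, stats

import litterbmd as lb
from litterbmd.dose_response import (
    PROFILE_CUTOFF_95,
    _qll_probs,
    extra_risk_bmd,
)
from litterbmd.errors import FitError, InsufficientDataError

from conftest import make_study


class TestResponseFunction:
    @pytest.mark.parametrize("alpha,beta", [(0.0, 1.0), (-2.0, 1.5), (3.0, 0.5)])
    def test_dose_zero_returns_background(self, alpha, beta):
        p = lb.QuantalLogLogisticParams(0.12, alpha, beta)
        assert lb.loglogistic_response(0.0, p) == pytest.approx(0.12)

    def test_logistic_midpoint(self):
        p = lb.QuantalLogLogisticParams(0.0, 0.0, 1.0)
        assert lb.loglogistic_response(1.0, p) == pytest.approx(0.5)

    def test_hand_evaluation(self):
        g, a, b, d = 0.1, -2.0, 1.5, 3.0
        expected = g + (1 - g) / (1 + math.exp(-a - b * math.log(d)))
        p = lb.QuantalLogLogisticParams(g, a, b)
        assert lb.loglogistic_response(d, p) == pytest.approx(expected, rel=1e-14)

    def test_nondecreasing_in_dose(self):
        p = lb.QuantalLogLogisticParams(0.05, -3.0, 1.2)
        doses = np.linspace(0, 50, 200)
        vals = lb.loglogistic_response(doses, p)
        assert np.all(np.diff(vals) >= -1e-15)


class TestBinomialKernel:
    def test_integer_counts_match_exact_pmf_minus_constant(self):
        k = lb.binomial_kernel_loglik(5, 15, 1 / 3)
        full = stats.binom.logpmf(5, 15, 1 / 3)
        const = math.log(math.comb(15, 5))
        assert k == pytest.approx(full - const, rel=1e-12)

    def test_zero_count_boundary_is_finite(self):
        assert lb.binomial_kernel_loglik(0.0, 10.0, 1e-9) == pytest.approx(
            10 * math.log1p(-1e-9))

    def test_linear_in_counts(self):
        k1 = lb.binomial_kernel_loglik(2.5, 7.5, 0.3)
        k2 = lb.binomial_kernel_loglik(5.0, 15.0, 0.3)
        assert k2 == pytest.approx(2 * k1, rel=1e-12)


class TestBetaBinomial:
    @pytest.mark.parametrize("a,n,pi", [(0, 5, 0.3), (3, 7, 0.6), (5, 5, 0.2)])
    def test_psi_zero_is_binomial(self, a, n, pi):
        assert lb.betabinomial_loglik(a, n, pi, 0.0) == pytest.approx(
            stats.binom.logpmf(a, n, pi), rel=1e-12)

    def test_uniform_mixing_case(self):
        # psi=1/3, pi=1/2 gives Beta(1,1): P(a | n=2) = 1/3 for each a
        for a in (0, 1, 2):
            ll = lb.betabinomial_loglik(a, 2, 0.5, 1 / 3)
            assert math.exp(ll) == pytest.approx(1 / 3, rel=1e-12)

    def test_single_trial_independent_of_psi(self):
        for psi in (0.0, 0.2, 0.7):
            assert lb.betabinomial_loglik(1, 1, 0.3, psi) == pytest.approx(
                math.log(0.3), rel=1e-12)

    def test_matches_scipy_betabinom(self):
        pi, psi, n = 0.35, 0.22, 12
        conc = (1 - psi) / psi
        for a in range(n + 1):
            mine = lb.betabinomial_loglik(a, n, pi, psi)
            ref = stats.betabinom.logpmf(a, n, pi * conc, (1 - pi) * conc)
            assert mine == pytest.approx(ref, rel=1e-10)

    def test_continuity_at_psi_boundary(self):
        near = lb.betabinomial_loglik(4, 11, 0.4, 1e-8)
        at = lb.betabinomial_loglik(4, 11, 0.4, 0.0)
        assert near == pytest.approx(at, abs=1e-5)


class TestClosedFormBmd:
    def test_alpha_zero_closed_form(self):
        assert extra_risk_bmd(0.0, 1.0, 0.05) == pytest.approx(0.05 / 0.95)

    def test_definitional_closure(self):
        p = lb.QuantalLogLogisticParams(0.07, -2.4, 1.3)
        bmd = extra_risk_bmd(p.intercept, p.slope, 0.05)
        risk = lb.extra_risk(lb.loglogistic_response(bmd, p), p.background)
        assert risk == pytest.approx(0.05, rel=1e-12)

    def test_matches_numeric_root(self):
        a, b, bmr = -3.0, 1.2, 0.05
        closed = extra_risk_bmd(a, b, bmr)
        root = optimize.brentq(
            lambda d: special.expit(a + b * math.log(d)) - bmr, 1e-8, 1e6)
        assert closed == pytest.approx(root, rel=1e-10)

    def test_nonpositive_slope_is_error(self):
        with pytest.raises(FitError):
            extra_risk_bmd(0.0, 0.0, 0.05)


def noiseless_groups(params, doses=(0.0, 5.0, 20.0, 80.0, 320.0), n=1e5):
    return [(d, n, n * lb.loglogistic_response(d, params)) for d in doses]


class TestQuantalFit:
    def test_recovery_on_noiseless_data(self):
        true = lb.QuantalLogLogisticParams(0.08, -4.0, 1.3)
        fit = lb.fit_quantal_loglogistic(noiseless_groups(true))
        assert fit.converged
        assert fit.params.background == pytest.approx(0.08, abs=1e-3)
        assert fit.params.intercept == pytest.approx(-4.0, abs=0.02)
        assert fit.params.slope == pytest.approx(1.3, abs=0.01)

    def test_flat_response_hits_slope_bound(self):
        groups = [(d, 50.0, 10.0) for d in (0.0, 1.0, 10.0, 100.0)]
        fit = lb.fit_quantal_loglogistic(groups, slope_min=1.0)
        # no dose signal: either the slope pins to its bound or the curve is
        # pushed out of the dose range entirely
        assert (fit.params.slope == pytest.approx(1.0, abs=1e-4)
                or abs(fit.params.intercept) > 10)

    def test_loglik_beats_generating_params_and_grid_oracle(self):
        rng = np.random.default_rng(2)
        true = lb.QuantalLogLogisticParams(0.05, -5.0, 1.1)
        doses = np.array([0.0, 10.0, 50.0, 200.0])
        n = np.full(4, 120.0)
        a = rng.binomial(120, lb.loglogistic_response(doses, true)).astype(float)
        groups = list(zip(doses, n, a))
        fit = lb.fit_quantal_loglogistic(groups)

        def ll(g, al, be):
            return lb.binomial_kernel_loglik(a, n, _qll_probs(doses, g, al, be))

        assert fit.loglik >= ll(true.background, true.intercept,
                                true.slope) - 1e-9
        # coarse grid + local polish must not beat the multistart fit
        best = -np.inf
        for g in np.linspace(0, 0.15, 7):
            for al in np.linspace(-8, -2, 13):
                for be in np.linspace(0.5, 2.0, 7):
                    best = max(best, ll(g, al, be))
        res = optimize.minimize(
            lambda t: -ll(*t), fit.params.__dict__.__class__ and
            [fit.params.background, fit.params.intercept, fit.params.slope],
            method="Nelder-Mead")
        assert fit.loglik >= best - 1e-6
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_gof_pearson_on_effective_counts(self):
        true = lb.QuantalLogLogisticParams(0.05, -4.0, 1.0)
        fit = lb.fit_quantal_loglogistic(noiseless_groups(true))
        assert fit.gof_df == 2
        assert fit.gof_stat == pytest.approx(0.0, abs=1e-4)
        assert fit.gof_p == pytest.approx(1.0, abs=1e-4)


@pytest.fixture(scope="module")
def stochastic_fit():
    rng = np.random.default_rng(4)
    true = lb.QuantalLogLogisticParams(0.05, -5.5, 1.2)
    doses = np.array([0.0, 25.0, 100.0, 400.0])
    n = np.full(4, 40.0)
    a = rng.binomial(40, lb.loglogistic_response(doses, true)).astype(float)
    return lb.fit_quantal_loglogistic(list(zip(doses, n, a)))


class TestProfileBmdl:

    def test_bmdl_below_bmd(self, stochastic_fit):
        bmd = lb.bmd_from_fit(stochastic_fit, 0.05)
        bmdl, warns = lb.profile_bmdl(stochastic_fit, 0.05)
        assert not warns
        assert bmdl < bmd

    def test_bmdl_decreases_with_confidence(self, stochastic_fit):
        b90, _ = lb.profile_bmdl(stochastic_fit, 0.05, confidence=0.90)
        b95, _ = lb.profile_bmdl(stochastic_fit, 0.05, confidence=0.95)
        b99, _ = lb.profile_bmdl(stochastic_fit, 0.05, confidence=0.99)
        assert b99 < b95 < b90

    def test_confidence_near_half_returns_bmd(self, stochastic_fit):
        bmd = lb.bmd_from_fit(stochastic_fit, 0.05)
        bmdl, _ = lb.profile_bmdl(stochastic_fit, 0.05, confidence=0.5001)
        assert bmdl == pytest.approx(bmd, rel=0.02)

    def test_matches_dense_grid_oracle(self, stochastic_fit):
        """Brute-force profile: dense BMD grid, full inner optimization."""
        fit = stochastic_fit
        bmd = lb.bmd_from_fit(fit, 0.05)
        bmdl, _ = lb.profile_bmdl(fit, 0.05)
        d = fit.data
        lbmr = special.logit(0.05)

        def pll(B):
            def negll(t):
                g, b = t
                al = lbmr - b * math.log(B)
                return -lb.binomial_kernel_loglik(
                    d["eff_a"], d["eff_n"],
                    _qll_probs(d["doses"], g, al, b))
            best = np.inf
            for g0 in (0.01, 0.05, 0.15):
                for b0 in (0.8, 1.2, 2.0):
                    r = optimize.minimize(
                        negll, [g0, b0], method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-10,
                                 "maxiter": 4000})
                    best = min(best, r.fun)
            return -best

        grid = np.exp(np.linspace(math.log(bmd / 20), math.log(bmd), 400))
        vals = np.array([pll(B) for B in grid])
        target = max(vals.max(), fit.loglik) - PROFILE_CUTOFF_95
        oracle = grid[np.argmax(vals >= target)]
        assert bmdl == pytest.approx(oracle, rel=2e-2)

    def test_dose_rescaling_invariance(self, stochastic_fit):
        d = stochastic_fit.data
        scaled = [(dose * 7.0, n, a) for dose, n, a in
                  zip(d["doses"], d["eff_n"], d["eff_a"])]
        fit2 = lb.fit_quantal_loglogistic(scaled)
        bmd1 = lb.bmd_from_fit(stochastic_fit, 0.05)
        bmd2 = lb.bmd_from_fit(fit2, 0.05)
        bmdl1, _ = lb.profile_bmdl(stochastic_fit, 0.05)
        bmdl2, _ = lb.profile_bmdl(fit2, 0.05)
        assert bmd2 == pytest.approx(7 * bmd1, rel=1e-4)
        assert bmdl2 == pytest.approx(7 * bmdl1, rel=1e-3)


class TestNestedFit:
    def test_reduces_to_quantal_when_no_clustering(self):
        cfg = lb.species_config(
            "mouse", seed=21,
            intralitter_corr=(0.0, 0.0, 0.0, 0.0),
            litters_per_group=(40, 40, 40, 40))
        study = lb.simulate_study(cfg)
        nll = lb.fit_nested_loglogistic(study)
        assert all(p < 0.06 for p in nll.params.intralitter_corr)
        groups = [(s.dose, s.n_fetuses, s.n_affected)
                  for s in lb.summarize_study(study)]
        qll = lb.fit_quantal_loglogistic(groups)
        bmd_n = lb.bmd_from_fit(nll, 0.05)
        bmd_q = lb.bmd_from_fit(qll, 0.05)
        assert bmd_n == pytest.approx(bmd_q, rel=0.10)

    def test_mle_dominates_generating_params(self, simulated_study):
        from litterbmd.dose_response import _nll_loglik, _study_arrays

        fit = lb.fit_nested_loglogistic(simulated_study)
        doses, sizes, affected = _study_arrays(simulated_study)
        theta_true = np.array([0.05, -6.0, 1.0, 0.13, 0.13, 0.13, 0.13])
        assert fit.loglik >= _nll_loglik(theta_true, doses, sizes,
                                         affected) - 1e-9

    def test_single_litter_group_raises(self):
        study = make_study({0.0: [(5, 0), (5, 1)], 1.0: [(5, 1)],
                            2.0: [(5, 3), (5, 2)]})
        with pytest.raises(InsufficientDataError, match="single litter"):
            lb.fit_nested_loglogistic(study)

    def test_parameter_recovery_generous_n(self):
        cfg = lb.species_config(
            "mouse", seed=33, litters_per_group=(80, 80, 80, 80))
        fit = lb.fit_nested_loglogistic(lb.simulate_study(cfg))
        assert fit.params.base.background == pytest.approx(0.05, abs=0.03)
        assert fit.params.base.intercept == pytest.approx(-6.0, abs=1.0)
        assert fit.params.base.slope == pytest.approx(1.0, abs=0.25)
        for psi in fit.params.intralitter_corr:
            assert psi == pytest.approx(0.13, abs=0.10)


class TestHillMeans:
    def hill_summaries(self, gamma=0.06, k=40.0, h=1.2, sd=0.12, nl=25):
        params = lb.HillContinuousParams(gamma, k, h, "constant", (sd**2,))
        doses = (0.0, 10.0, 40.0, 160.0)
        return [
            lb.GroupSummary(dose=d, n_fetuses=11 * nl, n_affected=0.0,
                            n_litters=nl, n_affected_litters=0,
                            p_avg=float(params.mean(d)), sd_litter_prop=sd)
            for d in doses
        ]

    def test_noiseless_recovery(self):
        fit = lb.fit_hill_means(self.hill_summaries())
        assert fit.converged
        assert fit.params.background_mean == pytest.approx(0.06, abs=1e-3)
        assert fit.params.half_max_dose == pytest.approx(40.0, rel=0.02)
        assert fit.params.hill_power == pytest.approx(1.2, abs=0.02)
        assert fit.gof_p > 0.99

    def test_constant_variance_matches_pooled_sd(self):
        fit = lb.fit_hill_means(self.hill_summaries(sd=0.12))
        sigma2 = fit.params.variance_params[0]
        # identical group SDs: ML pooled variance is (N_L-1)/N_L * S^2
        assert sigma2 == pytest.approx(24 / 25 * 0.12**2, rel=1e-3)

    def test_bmd_matches_quantal_when_parameters_matched(self):
        # the asymptote-1 Hill is the log-logistic with beta=h, alpha=-h*ln(k)
        fit = lb.fit_hill_means(self.hill_summaries())
        h = fit.params.hill_power
        k = fit.params.half_max_dose
        bmd_hill = lb.bmd_from_fit(fit, 0.05)
        bmd_qll = extra_risk_bmd(-h * math.log(k), h, 0.05)
        assert bmd_hill == pytest.approx(bmd_qll, rel=1e-10)

    def test_power_variance_mode_runs(self):
        fit = lb.fit_hill_means(self.hill_summaries(), variance_model="power")
        assert fit.converged
        assert len(fit.params.variance_params) == 2
        bmdl, _ = lb.profile_bmdl(fit, 0.05)
        assert 0 < bmdl <= lb.bmd_from_fit(fit, 0.05)

    def test_missing_sd_raises(self):
        bad = self.hill_summaries()
        bad[1] = lb.GroupSummary(dose=10.0, n_fetuses=275, n_affected=0.0,
                                 n_litters=25, n_affected_litters=0,
                                 p_avg=0.1, sd_litter_prop=math.nan)
        with pytest.raises(InsufficientDataError):
            lb.fit_hill_means(bad)
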