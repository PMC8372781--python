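"""Dose-response models, maximum-likelihood fitting, and BMD/BMDL inference.

Three model families share one dose-response shape:

* quantal log-logistic for (effective) binomial counts,
      P(d) = gamma + (1 - gamma) / (1 + exp(-alpha - beta * ln d)),  P(0) = gamma
* nested log-logistic (NLL): same mean curve with beta-binomial litter-level
  variability, one intralitter correlation psi_g per dose group,
* Hill model for continuous group means of litter proportions with the
  asymptote fixed at 1 — algebraically the same curve with
  beta = h (Hill power) and alpha = -h * ln k (half-maximal dose k).

With extra risk R(d) = (P(d) - P(0)) / (1 - P(0)) = 1/(1 + exp(-alpha -
beta ln d)), the benchmark dose at benchmark response ``bmr`` has the closed
form BMD = exp[(logit(bmr) - alpha) / beta] for every family. The BMDL is
the profile-likelihood lower confidence limit: the model is reparameterized
with the BMD explicit (alpha = logit(bmr) - beta ln BMD), nuisance
parameters are re-maximized at each candidate BMD, and the limit is where
the profile log-likelihood drops 1.35277 units (half the 90% chi-square(1)
quantile) below the maximum — the usual convention for a 95% one-sided
bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .data_model import GroupSummary, LitterStudy
from .design_effect import TransformedGroup
from .errors import FitError, InsufficientDataError

PROFILE_CUTOFF_95 = 1.352771727  # 0.5 * chi2(1).ppf(0.90)

_PCLIP = 1e-12


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class QuantalLogLogisticParams:
    background: float  # gamma
    intercept: float  # alpha
    slope: float  # beta

    def __post_init__(self) -> None:
        if not 0 <= self.background < 1:
            raise ValueError("background must be in [0, 1)")

    def response(self, dose) -> np.ndarray | float:
        return loglogistic_response(dose, self)

    def extra_risk_at(self, dose: float) -> float:
        """Extra risk at a dose; free of the background parameter."""
        if dose <= 0:
            return 0.0
        return float(special.expit(self.intercept + self.slope * math.log(dose)))


@dataclass(frozen=True)
class NestedLogLogisticParams:
    base: QuantalLogLogisticParams
    intralitter_corr: tuple[float, ...]  # psi_g, one per dose group

    def __post_init__(self) -> None:
        if any(not 0 <= p < 1 for p in self.intralitter_corr):
            raise ValueError("intralitter correlations must be in [0, 1)")


@dataclass(frozen=True)
class HillContinuousParams:
    """Hill mean curve m(d) = gamma + (1-gamma) d^h / (k^h + d^h) with the
    asymptote fixed at 1, plus a variance model for group means."""

    background_mean: float  # gamma
    half_max_dose: float  # k
    hill_power: float  # h
    variance_model: str  # "constant" | "power"
    variance_params: tuple[float, ...]  # (sigma2,) or (v, w)

    def mean(self, dose) -> np.ndarray | float:
        d = np.asarray(dose, dtype=float)
        g, k, h = self.background_mean, self.half_max_dose, self.hill_power
        frac = np.where(
            d > 0,
            special.expit(h * (np.log(np.maximum(d, 1e-300)) - math.log(k))),
            0.0,
        )
        out = g + (1 - g) * frac
        return float(out) if np.isscalar(dose) else out

    def group_variance(self, mean: np.ndarray) -> np.ndarray:
        if self.variance_model == "constant":
            return np.full_like(np.asarray(mean, dtype=float), self.variance_params[0])
        v, w = self.variance_params
        return v * np.maximum(np.asarray(mean, dtype=float), 1e-8) ** w


@dataclass
class ModelFit:
    model: str
    params: Any
    loglik: float
    converged: bool
    gof_stat: float
    gof_df: int
    gof_p: float
    n_params: int
    data: Any = field(repr=False, default=None)
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BmdResult:
    bmr: float
    risk_type: str
    bmd: float
    bmdl: float
    confidence: float = 0.95
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.bmdl <= self.bmd * (1 + 1e-9):
            raise ValueError("BMDL must not exceed BMD")


# ---------------------------------------------------------------------------
# Elementary pieces


def loglogistic_response(dose, params: QuantalLogLogisticParams):
    """P(d) = gamma + (1-gamma)/(1+exp(-alpha-beta ln d)); P(0) = gamma."""
    d = np.asarray(dose, dtype=float)
    g, a, b = params.background, params.intercept, params.slope
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log(np.maximum(d, 1e-300)), -np.inf)
    frac = special.expit(a + b * logd)
    frac = np.where(d > 0, frac, 0.0)
    out = g + (1 - g) * frac
    return float(out) if np.isscalar(dose) else out


def binomial_kernel_loglik(eff_a, eff_n, probability) -> float:
    """Binomial log-likelihood kernel for (possibly fractional) counts:
    eff_a*ln(p) + (eff_n-eff_a)*ln(1-p), omitting the combinatorial constant.

    Boundary handling: a zero count contributes nothing through its log term;
    p of exactly 0 or 1 against interior counts yields -inf.
    """
    a = np.asarray(eff_a, dtype=float)
    n = np.asarray(eff_n, dtype=float)
    p = np.asarray(probability, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(a > 0, a * np.log(p), 0.0)
        t2 = np.where(n - a > 0, (n - a) * np.log1p(-p), 0.0)
    out = t1 + t2
    return float(np.sum(out))


def betabinomial_loglik(a, n, mean_prob: float, intralitter_corr: float):
    """Beta-binomial log-pmf with mean ``mean_prob`` and intraclass
    correlation ``intralitter_corr`` (psi); psi = 0 reduces exactly to the
    binomial log-pmf. Vectorized over (a, n)."""
    if not 0 < mean_prob < 1:
        raise ValueError("mean_prob must be in (0, 1)")
    if not 0 <= intralitter_corr < 1:
        raise ValueError("intralitter_corr must be in [0, 1)")
    a_arr = np.asarray(a, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(a_arr < 0) or np.any(a_arr > n_arr):
        raise ValueError("need 0 <= a <= n")
    if intralitter_corr < 1e-12:
        out = stats.binom.logpmf(np.round(a_arr).astype(int),
                                 np.round(n_arr).astype(int), mean_prob)
    else:
        conc = (1 - intralitter_corr) / intralitter_corr
        s1 = mean_prob * conc
        s2 = (1 - mean_prob) * conc
        out = (
            special.gammaln(n_arr + 1)
            - special.gammaln(a_arr + 1)
            - special.gammaln(n_arr - a_arr + 1)
            + special.betaln(a_arr + s1, n_arr - a_arr + s2)
            - special.betaln(s1, s2)
        )
    return float(out) if np.isscalar(a) and np.isscalar(n) else out


def extra_risk_bmd(intercept: float, slope: float, bmr: float) -> float:
    """Closed-form BMD of the log-logistic family at extra risk ``bmr``."""
    if slope <= 0:
        raise FitError("BMD undefined: slope must be positive")
    if not 0 < bmr < 1:
        raise ValueError("bmr must be in (0, 1)")
    return math.exp((special.logit(bmr) - intercept) / slope)


# ---------------------------------------------------------------------------
# Quantal log-logistic fit


def _as_arrays(groups: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    doses, ns, as_ = [], [], []
    for g in groups:
        if isinstance(g, TransformedGroup):
            doses.append(g.dose), ns.append(g.eff_n), as_.append(g.eff_a)
        else:
            d, n, a = g
            doses.append(d), ns.append(n), as_.append(a)
    return (np.asarray(doses, float), np.asarray(ns, float), np.asarray(as_, float))


def _qll_probs(doses, gamma, alpha, beta):
    with np.errstate(divide="ignore"):
        logd = np.where(doses > 0, np.log(np.maximum(doses, 1e-300)), -np.inf)
    frac = np.where(doses > 0, special.expit(alpha + beta * logd), 0.0)
    return np.clip(gamma + (1 - gamma) * frac, _PCLIP, 1 - _PCLIP)


def _minimize(fun, x0, bounds):
    res = optimize.minimize(fun, x0, method="L-BFGS-B", bounds=bounds)
    # Nelder-Mead polish within bounds for a sharper optimum
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def clipped(x):
        return fun(np.clip(x, lo, hi))

    res2 = optimize.minimize(
        clipped, res.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
    )
    if res2.fun < res.fun:
        return np.clip(res2.x, lo, hi), res2.fun, True
    return res.x, res.fun, bool(res.success)


def fit_quantal_loglogistic(
    groups: Sequence, slope_min: float = 0.0
) -> ModelFit:
    """Maximum-likelihood quantal log-logistic fit to (effective) counts.

    ``groups`` is a sequence of :class:`TransformedGroup` or (dose, n, a)
    triples. ``slope_min`` of 1.0 applies the common beta >= 1 restriction.
    Goodness of fit is the Pearson chi-square on effective counts with
    df = groups - 3.
    """
    doses, ns, as_ = _as_arrays(groups)
    if len(doses) < 2 or not np.any(doses > 0):
        raise InsufficientDataError("need >= 2 dose groups incl. a nonzero dose")

    beta_lo = max(slope_min, 1e-6)

    def negll(theta):
        g, a, b = theta
        p = _qll_probs(doses, g, a, b)
        return -binomial_kernel_loglik(as_, ns, p)

    props = as_ / ns
    p0 = props[doses == 0].mean() if np.any(doses == 0) else props.min()
    top = np.argmax(doses)
    starts = []
    for g0 in {min(max(p0 * 0.9, 1e-4), 0.95), 1e-3}:
        for b0 in (0.5, 1.0, 2.0):
            r_top = (props[top] - g0) / (1 - g0)
            r_top = min(max(r_top, 1e-3), 1 - 1e-3)
            a0 = special.logit(r_top) - b0 * math.log(doses[top])
            starts.append((g0, a0, max(b0, beta_lo)))
    bounds = [(0.0, 0.9999), (-200.0, 200.0), (beta_lo, 100.0)]
    best = None
    for x0 in starts:
        x, f, ok = _minimize(negll, np.asarray(x0), bounds)
        if best is None or f < best[1]:
            best = (x, f, ok)
    x, f, ok = best
    params = QuantalLogLogisticParams(float(x[0]), float(x[1]), float(x[2]))

    phat = _qll_probs(doses, *x)
    gof_stat = float(np.sum((as_ - ns * phat) ** 2 / (ns * phat * (1 - phat))))
    gof_df = len(doses) - 3
    gof_p = float(stats.chi2.sf(gof_stat, gof_df)) if gof_df > 0 else math.nan
    return ModelFit(
        model="quantal_loglogistic",
        params=params,
        loglik=-f,
        converged=ok and math.isfinite(f),
        gof_stat=gof_stat,
        gof_df=gof_df,
        gof_p=gof_p,
        n_params=3,
        data={"doses": doses, "eff_n": ns, "eff_a": as_, "slope_min": slope_min},
    )


# ---------------------------------------------------------------------------
# Nested log-logistic fit (litter-level beta-binomial)


def _study_arrays(study: LitterStudy):
    doses = np.array([g.dose for g in study.groups], dtype=float)
    sizes = [np.array([r.size for r in g.litters], float) for g in study.groups]
    affected = [np.array([r.affected for r in g.litters], float) for g in study.groups]
    return doses, sizes, affected


def _nll_loglik(theta, doses, sizes, affected):
    g, al, be = theta[:3]
    psis = theta[3:]
    pis = _qll_probs(doses, g, al, be)
    pis = np.clip(pis, 1e-9, 1 - 1e-9)
    total = 0.0
    for j in range(len(doses)):
        total += float(np.sum(betabinomial_loglik(affected[j], sizes[j],
                                                  float(pis[j]), float(psis[j]))))
    return total


def fit_nested_loglogistic(
    study: LitterStudy, slope_min: float = 0.0, psi_max: float = 0.95
) -> ModelFit:
    """Fit the nested log-logistic: quantal log-logistic mean curve with
    beta-binomial litter variability, one intralitter correlation per dose
    group. Goodness of fit is a litter-level Pearson statistic with
    beta-binomial (design-effect-inflated) variances."""
    if len(study.groups) < 3:
        raise InsufficientDataError("need >= 3 dose groups for the nested fit")
    for g in study.groups:
        if g.n_litters < 2:
            raise InsufficientDataError(
                f"dose group {g.dose} has a single litter; merge or drop it"
            )
    doses, sizes, affected = _study_arrays(study)
    n_groups = len(doses)
    beta_lo = max(slope_min, 1e-6)

    def negll(theta):
        return -_nll_loglik(theta, doses, sizes, affected)

    props = np.array([a.sum() / n.sum() for a, n in zip(affected, sizes)])
    p0 = props[0] if doses[0] == 0 else props.min()
    g0 = min(max(p0, 1e-3), 0.9)
    top = np.argmax(doses)
    starts = []
    for b0 in (0.7, 1.0, 1.5):
        for psi0 in (0.05, 0.25):
            r_top = min(max((props[top] - g0) / (1 - g0), 1e-3), 1 - 1e-3)
            a0 = special.logit(r_top) - b0 * math.log(doses[top])
            starts.append([g0 * 0.9, a0, b0] + [psi0] * n_groups)
    bounds = [(0.0, 0.9999), (-200.0, 200.0), (beta_lo, 100.0)] + [
        (0.0, psi_max)
    ] * n_groups
    best = None
    for x0 in starts:
        x, f, ok = _minimize(negll, np.asarray(x0), bounds)
        if best is None or f < best[1]:
            best = (x, f, ok)
    x, f, ok = best
    base = QuantalLogLogisticParams(float(x[0]), float(x[1]), float(x[2]))
    psis = tuple(float(v) for v in x[3:])
    params = NestedLogLogisticParams(base=base, intralitter_corr=psis)

    # litter-level Pearson gof with variance n*pi*(1-pi)*(1+(n-1)*psi)
    pis = _qll_probs(doses, *x[:3])
    stat = 0.0
    n_litters = 0
    for j in range(n_groups):
        var = sizes[j] * pis[j] * (1 - pis[j]) * (1 + (sizes[j] - 1) * psis[j])
        stat += float(np.sum((affected[j] - sizes[j] * pis[j]) ** 2 / var))
        n_litters += len(sizes[j])
    n_params = 3 + n_groups
    gof_df = n_litters - n_params
    gof_p = float(stats.chi2.sf(stat, gof_df)) if gof_df > 0 else math.nan
    return ModelFit(
        model="nested_loglogistic",
        params=params,
        loglik=-f,
        converged=ok and math.isfinite(f),
        gof_stat=stat,
        gof_df=gof_df,
        gof_p=gof_p,
        n_params=n_params,
        data={"doses": doses, "sizes": sizes, "affected": affected,
              "slope_min": slope_min, "psi_max": psi_max},
    )


# ---------------------------------------------------------------------------
# Hill model on group means of litter proportions


def _hill_mean(doses, gamma, k, h):
    with np.errstate(divide="ignore"):
        frac = np.where(doses > 0,
                        special.expit(h * (np.log(np.maximum(doses, 1e-300))
                                           - math.log(k))), 0.0)
    return gamma + (1 - gamma) * frac


def _normal_summary_loglik(n, ybar, s, mean, var):
    var = np.maximum(var, 1e-12)
    return float(np.sum(-0.5 * n * np.log(2 * math.pi * var)
                        - ((n - 1) * s**2 + n * (ybar - mean) ** 2) / (2 * var)))


def fit_hill_means(
    summaries: Sequence[GroupSummary],
    variance_model: str = "constant",
) -> ModelFit:
    """Fit the asymptote-1 Hill curve to group means of litter proportions
    by the normal likelihood for summary data (per group: N_L litters, mean
    P_av, SD S).

    ``variance_model`` is ``"constant"`` (one pooled sigma^2) or ``"power"``
    (sigma^2 = v * mean^w). Reported gof is the likelihood-ratio test of the
    fitted means against group-specific means (same variance structure); a
    companion variance-adequacy test is in ``diagnostics``.
    """
    if len(summaries) < 3:
        raise InsufficientDataError("need >= 3 dose groups")
    if any(math.isnan(s.sd_litter_prop) or math.isnan(s.p_avg) for s in summaries):
        raise InsufficientDataError("every group needs P_av and S defined")
    doses = np.array([s.dose for s in summaries], float)
    nl = np.array([s.n_litters for s in summaries], float)
    ybar = np.array([s.p_avg for s in summaries], float)
    sd = np.array([s.sd_litter_prop for s in summaries], float)
    n_groups = len(summaries)

    if variance_model == "constant":
        n_var = 1
    elif variance_model == "power":
        n_var = 2
    else:
        raise ValueError(f"unknown variance model {variance_model!r}")

    def unpack(theta):
        g = theta[0]
        k = math.exp(theta[1])
        h = math.exp(theta[2])
        return g, k, h, theta[3:]

    def group_var(mean, vpar):
        if variance_model == "constant":
            return np.full_like(mean, math.exp(vpar[0]))
        return math.exp(vpar[0]) * np.maximum(mean, 1e-8) ** vpar[1]

    def negll(theta):
        g, k, h, vpar = unpack(theta)
        m = _hill_mean(doses, g, k, h)
        return -_normal_summary_loglik(nl, ybar, sd, m, group_var(m, vpar))

    pooled_var = float(np.sum((nl - 1) * sd**2) / np.sum(nl))
    dpos = doses[doses > 0]
    starts = []
    for k0 in (np.median(dpos), dpos.max()):
        for h0 in (0.7, 1.0, 2.0):
            v0 = ([math.log(max(pooled_var, 1e-6))]
                  if variance_model == "constant"
                  else [math.log(max(pooled_var, 1e-6)), 0.0])
            starts.append([min(max(ybar[0], 1e-3), 0.5),
                           math.log(k0), math.log(h0)] + v0)
    bounds = [(0.0, 0.9999), (-30.0, 30.0), (math.log(1e-3), math.log(50.0))]
    bounds += ([(-40.0, 10.0)] if variance_model == "constant"
               else [(-40.0, 10.0), (-5.0, 5.0)])
    best = None
    for x0 in starts:
        x, f, ok = _minimize(negll, np.asarray(x0), bounds)
        if best is None or f < best[1]:
            best = (x, f, ok)
    x, f, ok = best
    g, k, h, vpar = unpack(x)
    if variance_model == "constant":
        var_params = (math.exp(vpar[0]),)
    else:
        var_params = (math.exp(vpar[0]), float(vpar[1]))
    params = HillContinuousParams(
        background_mean=float(g),
        half_max_dose=float(k),
        hill_power=float(h),
        variance_model=variance_model,
        variance_params=var_params,
    )

    # saturated references (means fixed at observed group averages)
    var_g_ml = (nl - 1) * sd**2 / nl  # per-group ML variances
    ll_sat = _normal_summary_loglik(nl, ybar, sd, ybar, np.maximum(var_g_ml, 1e-12))
    if variance_model == "constant":
        ll_a3 = _normal_summary_loglik(nl, ybar, sd, ybar,
                                       np.full(n_groups, max(pooled_var, 1e-12)))
    else:
        def neg_a3(vpar):
            return -_normal_summary_loglik(nl, ybar, sd, ybar,
                                           group_var(ybar, vpar))
        x3, f3, _ = _minimize(neg_a3, np.asarray(
            [math.log(max(pooled_var, 1e-6)), 0.0]),
            [(-40.0, 10.0), (-5.0, 5.0)])
        ll_a3 = -f3

    mean_stat = max(2 * (ll_a3 - (-f)), 0.0)
    mean_df = n_groups - 3
    mean_p = float(stats.chi2.sf(mean_stat, mean_df)) if mean_df > 0 else math.nan
    var_stat = max(2 * (ll_sat - ll_a3), 0.0)
    var_df = n_groups - n_var
    var_p = float(stats.chi2.sf(var_stat, var_df)) if var_df > 0 else math.nan

    return ModelFit(
        model="hill_means",
        params=params,
        loglik=-f,
        converged=ok and math.isfinite(f),
        gof_stat=mean_stat,
        gof_df=mean_df,
        gof_p=mean_p,
        n_params=3 + n_var,
        data={"doses": doses, "n_litters": nl, "ybar": ybar, "sd": sd,
              "variance_model": variance_model},
        diagnostics={"variance_gof_stat": var_stat, "variance_gof_df": var_df,
                     "variance_gof_p": var_p, "loglik_saturated": ll_sat,
                     "loglik_means_saturated": ll_a3},
    )


# ---------------------------------------------------------------------------
# BMD and profile BMDL


def bmd_from_fit(fit: ModelFit, bmr: float, risk_type: str = "extra") -> float:
    """Benchmark dose at extra risk ``bmr`` from a fitted model (closed form;
    independent of the background for the log-logistic family)."""
    if risk_type != "extra":
        raise ValueError("only extra risk is supported")
    if fit.model in ("quantal_loglogistic",):
        p = fit.params
        return extra_risk_bmd(p.intercept, p.slope, bmr)
    if fit.model == "nested_loglogistic":
        p = fit.params.base
        return extra_risk_bmd(p.intercept, p.slope, bmr)
    if fit.model == "hill_means":
        p = fit.params
        # mean-scale extra risk (m(B)-m(0))/(1-m(0)) = bmr  =>  F(B) = bmr
        return p.half_max_dose * (bmr / (1 - bmr)) ** (1 / p.hill_power)
    raise FitError(f"unknown model {fit.model!r}")


def _profile_fn(fit: ModelFit, bmr: float) -> Callable[[float], float]:
    """Return pll(B): the log-likelihood re-maximized over nuisance
    parameters with the BMD held at B. Warm-starts between calls."""
    lbmr = float(special.logit(bmr))
    state: dict[str, np.ndarray] = {}

    if fit.model == "quantal_loglogistic":
        d = fit.data
        doses, ns, as_ = d["doses"], d["eff_n"], d["eff_a"]
        beta_lo = max(d.get("slope_min", 0.0), 1e-6)
        p = fit.params
        state["x"] = np.array([p.background, p.slope])
        bounds = [(0.0, 0.9999), (beta_lo, 100.0)]

        def pll(bmd: float) -> float:
            logb = math.log(bmd)

            def negll(t):
                g, b = t
                return -binomial_kernel_loglik(
                    as_, ns, _qll_probs(doses, g, lbmr - b * logb, b))

            x, f, _ = _minimize(negll, state["x"], bounds)
            state["x"] = x
            return -f

        return pll

    if fit.model == "nested_loglogistic":
        d = fit.data
        doses, sizes, affected = d["doses"], d["sizes"], d["affected"]
        beta_lo = max(d.get("slope_min", 0.0), 1e-6)
        p = fit.params
        state["x"] = np.array([p.base.background, p.base.slope,
                               *p.intralitter_corr])
        bounds = [(0.0, 0.9999), (beta_lo, 100.0)] + [
            (0.0, d.get("psi_max", 0.95))] * len(doses)

        def pll(bmd: float) -> float:
            logb = math.log(bmd)

            def negll(t):
                theta = np.concatenate(([t[0], lbmr - t[1] * logb, t[1]], t[2:]))
                return -_nll_loglik(theta, doses, sizes, affected)

            x, f, _ = _minimize(negll, state["x"], bounds)
            state["x"] = x
            return -f

        return pll

    if fit.model == "hill_means":
        d = fit.data
        doses, nl, ybar, sd = d["doses"], d["n_litters"], d["ybar"], d["sd"]
        variance_model = d["variance_model"]
        p = fit.params
        if variance_model == "constant":
            vstart = [math.log(p.variance_params[0])]
            vb = [(-40.0, 10.0)]
        else:
            vstart = [math.log(p.variance_params[0]), p.variance_params[1]]
            vb = [(-40.0, 10.0), (-5.0, 5.0)]
        state["x"] = np.array([p.background_mean, math.log(p.hill_power)] + vstart)
        bounds = [(0.0, 0.9999), (math.log(1e-3), math.log(50.0))] + vb
        rfac = math.log(bmr / (1 - bmr))

        def pll(bmd: float) -> float:
            def negll(t):
                g, logh = t[0], t[1]
                h = math.exp(logh)
                logk = min(max(math.log(bmd) - rfac / h, -600.0), 600.0)
                m = _hill_mean(doses, g, math.exp(logk), h)
                if variance_model == "constant":
                    var = np.full_like(m, math.exp(t[2]))
                else:
                    var = math.exp(t[2]) * np.maximum(m, 1e-8) ** t[3]
                return -_normal_summary_loglik(nl, ybar, sd, m, var)

            x, f, _ = _minimize(negll, state["x"], bounds)
            state["x"] = x
            return -f

        return pll

    raise FitError(f"profiling not supported for model {fit.model!r}")


def profile_bmdl(
    fit: ModelFit,
    bmr: float,
    confidence: float = 0.95,
    rel_tol: float = 1e-5,
) -> tuple[float, tuple[str, ...]]:
    """Profile-likelihood lower confidence limit on the BMD.

    Returns ``(bmdl, warnings)``. The cutoff is half the chi-square(1)
    quantile at probability ``2*confidence - 1`` (1.35277 units at 95%
    one-sided).
    """
    if not 0.5 < confidence < 1:
        raise ValueError("confidence must be in (0.5, 1)")
    bmd = bmd_from_fit(fit, bmr)
    cutoff = 0.5 * stats.chi2.ppf(2 * confidence - 1, 1)
    pll = _profile_fn(fit, bmr)
    ll_at_bmd = pll(bmd)
    llmax = max(fit.loglik, ll_at_bmd)
    target = llmax - cutoff

    warnings: list[str] = []
    lo, hi = None, bmd
    ll_hi = ll_at_bmd
    b = bmd
    for _ in range(200):
        b *= 0.7
        ll_b = pll(b)
        if ll_b < target:
            lo = b
            break
        hi, ll_hi = b, ll_b
        if b < bmd * 1e-12:
            break
    if lo is None:
        warnings.append("profile flat below BMD; returning lower search bound")
        return b, tuple(warnings)

    def g(logb):
        return pll(math.exp(logb)) - target

    try:
        logl = optimize.brentq(g, math.log(lo), math.log(hi),
                               xtol=rel_tol, rtol=8.9e-16)
        bmdl = math.exp(logl)
    except ValueError:
        warnings.append("profile bracketing failed; returning bracket midpoint")
        bmdl = math.sqrt(lo * hi)
    return min(bmdl, bmd), tuple(warnings)


def bmd_analysis(
    fit: ModelFit, bmr: float = 0.05, confidence: float = 0.95
) -> BmdResult:
    """BMD and profile BMDL at the stated benchmark response."""
    bmd = bmd_from_fit(fit, bmr)
    bmdl, warns = profile_bmdl(fit, bmr, confidence=confidence)
    return BmdResult(bmr=bmr, risk_type="extra", bmd=bmd, bmdl=bmdl,
                     confidence=confidence, warnings=warns)
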