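# Methods

## Data model and summary statistics

The unit of observation is the litter: `n_i` live fetuses, `a_i` affected.
Per dose group the package computes N_F = Σn_i, A_F = Σa_i, the ratio
estimator P_F = A_F/N_F, the litter count N_L, the count A_L and proportion
P_L = A_L/N_L of litters with any affected fetus, the unweighted mean P_av
of litter proportions p_i = a_i/n_i, and their sample standard deviation S
(divisor N_L − 1; undefined for singleton groups). The size-weighted mean
of litter proportions equals P_F identically — an invariant the test suite
checks at machine precision. P_av typically exceeds P_F slightly because
small litters get equal weight.

Pooled SD across groups (`pooled_litter_sd`) weights group variances by
degrees of freedom N_L − 1, the standard pooled-variance rule that makes
pooling exact when variances are homogeneous; weighting by fetus counts is
available as an option. Litters with zero live fetuses are rejected at
parse time: they carry no response information for a per-fetus risk
endpoint, and admitting size 0 would make every proportion undefined.

## Rao–Scott design effect

For a group with m ≥ 2 litters and 0 < P_F < 1,

    D = [m/(m−1) · Σ n_i² (p_i − P_F)² / N_F²]  /  [P_F(1−P_F)/N_F].

The numerator is the cluster-sample estimate of Var(P_F); the denominator
the naive binomial variance. One normalization subtlety: writing the
numerator with 1/N_F (a count-scale variance) instead of 1/N_F² would give
D = m²/(m−1) for independent Bernoulli litters, contradicting the
requirement that D ≈ 1 under independence. With the variance-of-proportion
normalization used here, m litters of size 1 give exactly D = m/(m−1) → 1,
and for equal litter size n with intraclass correlation ρ the estimator
tracks D = 1 + (n−1)ρ (verified by simulation in the test suite). Groups
with P_F ∈ {0, 1} have no defined D; the conventional substitution D = 1 is
applied by the orchestration layer. D < 1 (underdispersion) is allowed and
does occur; a floor-at-1 switch exists for conservative use (default off).

**Pooled design effect.** The study-level D_p sums per-group cluster
numerators and binomial denominators with each group centered at its own
P_F (degenerate groups skipped). Centering all litters at the study-wide
proportion instead would absorb the dose effect itself into the "design
effect"; that literal all-litters pooling is retained as
`center="study"` for comparison but is not the default.

**Historical prediction.** The regression ln D = a + b·ln P_F is fitted by
ordinary least squares (via statsmodels) or orthogonal (total) least
squares with unit error-variance ratio — the closed-form TLS slope
(S_yy − S_xx + √((S_yy−S_xx)² + 4S_xy²)) / 2S_xy — since both D and P_F
are estimated with error and no error-variance ratio is identifiable from
summary data. Predictions back-transform with the lognormal mean
correction D = exp(a + b·ln P_F + σ²_res/2) (mode `"mean"`; `"median"`
omits the correction, and is therefore never larger). Shipped per-species
coefficients (mouse/rat/rabbit, LS and OR) come from a historical database
of NTP/EPA developmental studies; the default prediction averages the LS
and OR predictions on the natural D scale — LS attenuates the slope under
errors-in-x while OR with an assumed unit variance ratio tends to
overstate it, so their average is a reasonable compromise. Log-scale
averaging is available by option. Users can refit on their own litter
collections and pass the resulting `HistoricalFit`s anywhere the shipped
constants are accepted.

**Transformation.** Effective counts are N_F/D and (chosen proportion)
· N_F/D, kept fractional (no rounding): the binomial likelihood kernel
a·ln p + (n−a)·ln(1−p) is well defined for fractional counts and avoids
rounding error. The transformation preserves the proportion exactly.

## Dose-response models

All three families share one curve. The quantal log-logistic is

    P(d) = γ + (1−γ) / (1 + exp(−α − β ln d)),    P(0) = γ,

with extra risk R(d) = (P(d)−P(0))/(1−P(0)) = expit(α + β ln d) — free of
γ — so the benchmark dose at benchmark response BMR has the closed form
BMD = exp[(logit(BMR) − α)/β]. The nested log-logistic (NLL) keeps this
mean curve and replaces the binomial litter likelihood with a
beta-binomial: shapes s₁ = π·(1−ψ)/ψ, s₂ = (1−π)(1−ψ)/ψ give mean π and
intraclass correlation ψ, estimated separately per dose group (litter-size
covariate terms are fixed at zero; an option exists but per-group ψ is the
model intended here). ψ = 0 reduces continuously to the binomial. The Hill
model for group means of litter proportions, with its asymptote fixed at
1, is m(d) = γ + (1−γ)·d^h/(k^h + d^h) — algebraically the log-logistic
with β = h and α = −h·ln k — fitted by the standard normal likelihood for
summary data (N_L, mean, SD per group), with either a single constant
variance or a power-of-the-mean variance σ² = v·m(d)^w. Its BMR is the
mean-scale extra-risk analog (m(BMD)−m(0))/(1−m(0)) = BMR, which reduces
to the same closed form; this keeps all three families targeting the same
quantity (absolute- or relative-change readings of a "5% increase" would
not).

**Fitting.** Maximum likelihood with multi-start L-BFGS-B from a
deterministic start grid, followed by a Nelder-Mead polish clipped to the
bounds. No global random state is touched. d = 0 is handled by the limit
P(0) = γ, never by evaluating ln 0; probabilities are clipped at 1e−12 for
the kernel.

**Slope restriction.** The library fitters default to β > 0 with an
optional β ≥ 1 restriction (`slope_min=1.0`). The orchestration layer
(`run_method`, `compare_methods`, `fit_baseline_nll`) applies β ≥ 1 by
default: with the slope free, the profile likelihood in the BMD direction
becomes nearly flat as BMD → 0 whenever effective sample sizes are small
(a few dozen per group), and BMDLs collapse by orders of magnitude — the
well-known supralinearity pathology that the standard restriction exists
to prevent. Comparisons between summary-data methods and the nested
baseline are only interpretable with both under the same restriction.

**Goodness of fit.** Quantal fits report the Pearson chi-square on
effective counts with df = groups − 3. The NLL reports a litter-level
Pearson statistic with beta-binomial variances n_iπ(1−π)(1+(n_i−1)ψ_g) and
df = litters − (3+G); with one ψ per group a group-level statistic would
have negative df. Hill fits report a likelihood-ratio test of the fitted
means against group-specific means under the same variance structure
(df = G − 3), plus a companion variance-adequacy LR test against
group-specific variances in `diagnostics`; for the power model the
means-saturated reference fixes means at the observed averages, a standard
and slightly conservative approximation.

**Profile BMDL.** The model is reparameterized with BMD explicit
(α = logit(BMR) − β·ln BMD); at each candidate BMD all nuisance parameters
(γ, β, and for the NLL every ψ_g; for Hill γ, h and the variance
parameters) are re-maximized, warm-starting from the neighboring solution.
The BMDL solves profile-ll(BMD) = max-ll − c with c = ½·χ²₁(2·conf − 1)
(1.35277 at 95% one-sided), located by geometric bracketing (factor 0.7)
and Brent's method on ln BMD. If the profile never drops below the cutoff
within 12 orders of magnitude the search bound is returned with a warning
flag. BMD and BMDL scale exactly with the dose unit (tested).

## Trend test and screening

The adjusted Cochran–Armitage statistic divides each group's A_F and N_F
by its design effect and applies the classical formula with literal dose
scores (rank scores by option, no continuity correction):

    z = Σ s_g(Ã_g − Ñ_g·p̄) / √[p̄(1−p̄)(Σ Ñ_g s_g² − (Σ Ñ_g s_g)²/Ñ)].

With all D = 1 this is exactly the classical test; multiplying all D by c
shrinks z by √c. Screening passes a study when the one-sided (increasing)
adjusted trend p < 0.05 and some dose group shows ≥ 5% extra risk over
control. One-sided is the natural choice for a screen that asks "does
response increase with dose"; the threshold and sidedness are arguments.

## Litter-risk relations

Under within-litter independence and constant litter size n,
P_L = 1 − (1−P_F)^n. Shipped historical fits on the log₁₀ scale:
orthogonal log-linear (0.622, 0.815), OLS log-linear (0.522, 0.761), and
an LS quadratic (0.031, 0.226, −0.141). In the region P_F ≤ 0.05 these
imply P_L/P_F ≈ 4–10, which is why affected-litter analyses need a much
larger BMR (the method suite uses 30–40% litter extra risk as the
counterpart of 5% fetal extra risk). Predictions above 1 are clipped with
a warning. Note a cosmetic wrinkle: evaluated at P_F = 0.05 the rounded
orthogonal coefficients give 0.364 rather than the 0.37 obtained from the
unrounded fit; the shipped constants are the published rounded values.

## The 15-method comparison

Methods 1–7 transform (A_F, N_F) by D_g (per-group), D_p (pooled), D_h
(historical prediction from each group's P_F, averaging LS and OR), 1, 2,
3, or the group mean litter size N_F/N_L (making N_L the effective N),
then fit the quantal log-logistic at BMR 0.05. Methods 8–10 repeat D = 1,
2, N_F/N_L with P_av in place of P_F (effective affected count =
P_av · N_F/D, i.e. the percentage is applied to the effective N). Methods
11–12 fit the Hill model (constant / power variance) to (P_av, S, N_L).
Methods 13–15 fit the quantal model to (A_L, N_L) at BMR 0.40, 0.30 and
0.05 respectively. Each method's BMD and BMDL are divided by the NLL
baseline values and reported as log₁₀ ratios; the baseline always requires
litter-level data, so summary-only inputs get absolute results with NaN
ratios. Per-method ratio collections summarize as mean, sample SD, and
RMSE = √(mean² + SD²); nonconverged or non-finite rows are excluded and
counted.

## Synthetic studies

`simulate_study` draws, per group: litter sizes (fixed, or a discretized
normal truncated at 1 — mouse 11±2.5, rat 13±2.5, rabbit 7±1.5, matching
typical live-litter sizes in the historical database), a per-litter
probability from the beta distribution with mean π(dose) and intraclass
correlation ρ_g (degenerate at π when ρ_g = 0), and binomial affected
counts. This is exactly the NLL generating process. The default study is a
mouse design with doses (0, 62.5, 125, 250) mg/kg-day, 24 dams per group,
background 5%, slope 1 and intercept −6 (≈ 41% response at the top dose;
generating BMD ≈ 21.2), and constant ρ = 0.13 per group — giving design
effects near 2.3 at litter size 11, the typical historical magnitude. An
option to let ρ rise with π exists in spirit via per-group ρ vectors; the
default keeps ρ constant across groups.

What the simulator does *not* emulate: dead implants and resorptions,
dose-dependent litter-size reduction, non-beta litter heterogeneity, and
multiple correlated endpoints. Passing recovery tests therefore
demonstrates correctness of the estimators under the nested model's own
assumptions, not robustness to these real-data departures.

## Problem sizes and numerical choices

The stochastic test-suite checks use 50 simulated studies for the
method-comparison claim and 100 replicates at 50 litters/group for
parameter recovery — sizes at which median-based assertions are stable
across seeds while the full suite stays fast enough for routine runs.
Tolerances: closed-form BMD vs numeric root 1e−8 relative; profile BMDL vs
dense-grid oracle 1e−3 relative; Monte-Carlo assertions use 3–4σ binomial
error bands. Optimizer ties are broken deterministically (fixed start
grids, warm starts); doses are compared exactly after parsing unless a
tolerance is requested.

## Known limitations

* The historical coefficients are shipped constants; the underlying
  database is not distributed, so they cannot be re-derived here.
* The NLL goodness-of-fit statistic is a pragmatic litter-level Pearson
  measure, not a bootstrap calibration; its p-values are approximate for
  small litters.
* Profile confidence limits assume the usual chi-square calibration, which
  degrades at parameter-space boundaries (γ̂ = 0, β̂ at its bound).
* No Bayesian or model-averaged BMD, no joint multi-outcome models, no
  exact permutation trend test.
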