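"""Shipped historical regression coefficients.

These constants summarize a historical database of NTP/EPA developmental
toxicity studies (55 studies; 241 dose groups) in which the design effect D
of each dose group was regressed on the proportion of malformed fetuses P_F
on the log-log scale,

    log_e(D) = a + b * log_e(P_F),

separately per species and by ordinary least squares (LS) and orthogonal
regression (OR). The residual variance sigma_res^2 (natural-log scale) feeds
the mean back-transform D = exp(a + b*ln(P_F) + sigma_res^2 / 2).

The raw historical data are not distributed with this package; users with
their own litter-level collections can refit via
:func:`litterbmd.design_effect.fit_design_effect_regression` and pass the
resulting fits anywhere these defaults are accepted.
"""

from __future__ import annotations

# (species, method) -> (a, b, resid_var, n_dose_groups)
HISTORICAL_DEFF_COEFFS: dict[tuple[str, str], tuple[float, float, float, int]] = {
    ("mouse", "LS"): (1.5938, 0.2866, 0.2078, 88),
    ("mouse", "OR"): (1.6943, 0.3132, 0.1863, 88),
    ("rat", "LS"): (1.6852, 0.3310, 0.1248, 101),
    ("rat", "OR"): (1.8327, 0.3690, 0.1090, 101),
    ("rabbit", "LS"): (1.0582, 0.2397, 0.1452, 43),
    ("rabbit", "OR"): (1.1477, 0.2739, 0.1299, 43),
}

# Historical litter-risk vs fetal-risk relations on the log10 scale,
# log10(P_L) = c0 + c1*log10(P_F) [+ c2*log10(P_F)^2], fitted on the same
# historical dose groups (those with P_F > 0; n = 232).
PL_PF_LOGLINEAR_OR: tuple[float, float] = (0.622, 0.815)
PL_PF_LOGLINEAR_LS: tuple[float, float] = (0.522, 0.761)
PL_PF_QUADRATIC_LS: tuple[float, float, float] = (0.031, 0.226, -0.141)
PL_PF_N_GROUPS: int = 232
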