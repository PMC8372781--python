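"""Orchestration of the 15 summary-data BMD methods and the nested baseline.

Methods 1-7 fit the quantal log-logistic to fetus counts (A_F, N_F) after a
Rao-Scott transformation with different design-effect rules; methods 8-10
substitute the mean of litter proportions P_av for the ratio estimator;
methods 11-12 fit the continuous Hill model to the mean and SD of litter
proportions; methods 13-15 fit the quantal model to affected-litter counts
(A_L of N_L) at progressively larger benchmark responses (a 5% fetal extra
risk corresponds to a much larger litter-level extra risk).

Each method's BMD/BMDL is compared with the nested log-logistic (NLL)
baseline fit on litter-level data as log10(BMD_method / BMD_NLL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GroupSummary, LitterStudy, summarize_study
from .design_effect import (
    DesignEffect,
    group_design_effect_or_one,
    pooled_design_effect,
    predict_design_effect,
    rao_scott_transform,
    study_design_effects,
    TransformedGroup,
)
from .dose_response import (
    BmdResult,
    ModelFit,
    bmd_analysis,
    fit_hill_means,
    fit_nested_loglogistic,
    fit_quantal_loglogistic,
)
from .errors import InsufficientDataError, LitterBmdError
from .risk_relations import adjusted_trend_test, extra_risk


@dataclass(frozen=True)
class MethodSpec:
    id: int
    data_basis: str  # counts_PF | mean_props_Pav | mean_sd_continuous | affected_litters
    design_effect_rule: str  # Dg | Dp | Dh | fixed1 | fixed2 | fixed3 | mean_litter_size | none
    model: str  # quantal_loglogistic | hill_const_var | hill_power_var
    bmr: float
    label: str


METHOD_SPECS: dict[int, MethodSpec] = {
    1: MethodSpec(1, "counts_PF", "Dg", "quantal_loglogistic", 0.05,
                  "N_F/D_g, P_F"),
    2: MethodSpec(2, "counts_PF", "Dp", "quantal_loglogistic", 0.05,
                  "N_F/D_p, P_F"),
    3: MethodSpec(3, "counts_PF", "Dh", "quantal_loglogistic", 0.05,
                  "N_F/D_h, P_F"),
    4: MethodSpec(4, "counts_PF", "fixed1", "quantal_loglogistic", 0.05,
                  "N_F, P_F (D=1)"),
    5: MethodSpec(5, "counts_PF", "fixed2", "quantal_loglogistic", 0.05,
                  "N_F/2, P_F"),
    6: MethodSpec(6, "counts_PF", "fixed3", "quantal_loglogistic", 0.05,
                  "N_F/3, P_F"),
    7: MethodSpec(7, "counts_PF", "mean_litter_size", "quantal_loglogistic",
                  0.05, "N_L, P_F"),
    8: MethodSpec(8, "mean_props_Pav", "fixed1", "quantal_loglogistic", 0.05,
                  "N_F, P_av (D=1)"),
    9: MethodSpec(9, "mean_props_Pav", "fixed2", "quantal_loglogistic", 0.05,
                  "N_F/2, P_av"),
    10: MethodSpec(10, "mean_props_Pav", "mean_litter_size",
                   "quantal_loglogistic", 0.05, "N_L, P_av"),
    11: MethodSpec(11, "mean_sd_continuous", "none", "hill_const_var", 0.05,
                   "Hill (vc)"),
    12: MethodSpec(12, "mean_sd_continuous", "none", "hill_power_var", 0.05,
                   "Hill (vm)"),
    13: MethodSpec(13, "affected_litters", "none", "quantal_loglogistic", 0.40,
                   "N_L, P_L @ 40% ER"),
    14: MethodSpec(14, "affected_litters", "none", "quantal_loglogistic", 0.30,
                   "N_L, P_L @ 30% ER"),
    15: MethodSpec(15, "affected_litters", "none", "quantal_loglogistic", 0.05,
                   "N_L, P_L @ 5% ER"),
}


@dataclass(frozen=True)
class ComparisonRow:
    method_id: int
    bmd: float
    bmdl: float
    log10_bmd_ratio: float
    log10_bmdl_ratio: float
    gof_p: float
    converged: bool
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class RatioSummary:
    mean: float
    sd: float
    rmse: float
    n: int


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    trend_p: float
    max_extra_risk: float
    reasons: tuple[str, ...]


def screen_study(
    study: LitterStudy,
    design_effects: Sequence[DesignEffect | float] | None = None,
    alpha: float = 0.05,
    min_extra_risk: float = 0.05,
) -> ScreenResult:
    """Screen a study for an unambiguous dose response: a significant
    design-effect-adjusted trend (one-sided p < alpha) AND at least
    ``min_extra_risk`` extra risk over control in some dose group."""
    if study.control is None:
        raise LitterBmdError("screening requires a control (dose 0) group")
    summaries = summarize_study(study)
    if design_effects is None:
        design_effects = study_design_effects(study)
    trend = adjusted_trend_test(summaries, design_effects)
    p0 = summaries[0].p_fetal
    max_er = max(
        (extra_risk(s.p_fetal, p0) for s in summaries[1:]), default=0.0
    )
    reasons = []
    if not trend.p_one_sided < alpha:
        reasons.append(
            f"no significant adjusted trend (one-sided p = "
            f"{trend.p_one_sided:.3g} >= {alpha})")
    if not max_er >= min_extra_risk:
        reasons.append(
            f"max extra risk over control {max_er:.3g} < {min_extra_risk}")
    return ScreenResult(
        passed=not reasons,
        trend_p=trend.p_one_sided,
        max_extra_risk=max_er,
        reasons=tuple(reasons),
    )


def _design_effects_for(
    study: LitterStudy, summaries: Sequence[GroupSummary], rule: str
) -> list[float]:
    if rule == "Dg":
        return [d.value for d in study_design_effects(study)]
    if rule == "Dp":
        return [pooled_design_effect(study).value] * len(summaries)
    if rule == "Dh":
        out = []
        for s in summaries:
            if s.p_fetal <= 0:
                out.append(1.0)  # degenerate group: conventional D = 1
            else:
                out.append(predict_design_effect(
                    species=study.species, p_fetal=s.p_fetal).value)
        return out
    if rule == "fixed1":
        return [1.0] * len(summaries)
    if rule == "fixed2":
        return [2.0] * len(summaries)
    if rule == "fixed3":
        return [3.0] * len(summaries)
    if rule == "mean_litter_size":
        return [s.mean_litter_size for s in summaries]
    raise ValueError(f"unknown design effect rule {rule!r}")


def fit_baseline_nll(
    study: LitterStudy, bmr: float = 0.05, confidence: float = 0.95,
    slope_min: float = 1.0,
) -> tuple[ModelFit, BmdResult]:
    """Fit the nested log-logistic baseline and its BMD/BMDL."""
    fit = fit_nested_loglogistic(study, slope_min=slope_min)
    return fit, bmd_analysis(fit, bmr=bmr, confidence=confidence)


def run_method(
    study: LitterStudy,
    spec: MethodSpec | int,
    baseline: BmdResult | None = None,
    confidence: float = 0.95,
    slope_min: float = 1.0,
) -> ComparisonRow:
    """Apply one summary-data method to a study and compare with the NLL
    baseline (log10 ratios are NaN when no baseline is given)."""
    if isinstance(spec, int):
        spec = METHOD_SPECS[spec]
    summaries = summarize_study(study)

    if spec.data_basis in ("counts_PF", "mean_props_Pav"):
        deffs = _design_effects_for(study, summaries, spec.design_effect_rule)
        response = "p_fetal" if spec.data_basis == "counts_PF" else "p_avg"
        if response == "p_avg" and any(math.isnan(s.p_avg) for s in summaries):
            raise InsufficientDataError(
                f"method {spec.id} needs the mean of litter proportions "
                "(p_avg) for every dose group")
        groups = [rao_scott_transform(s, d, response=response)
                  for s, d in zip(summaries, deffs)]
        fit = fit_quantal_loglogistic(groups, slope_min=slope_min)
    elif spec.data_basis == "mean_sd_continuous":
        variance_model = ("constant" if spec.model == "hill_const_var"
                          else "power")
        fit = fit_hill_means(summaries, variance_model=variance_model)
    elif spec.data_basis == "affected_litters":
        groups = [TransformedGroup(dose=s.dose, eff_n=s.n_litters,
                                   eff_a=s.n_affected_litters)
                  for s in summaries]
        fit = fit_quantal_loglogistic(groups, slope_min=slope_min)
    else:
        raise ValueError(f"unknown data basis {spec.data_basis!r}")

    res = bmd_analysis(fit, bmr=spec.bmr, confidence=confidence)
    if baseline is not None:
        lr_bmd = math.log10(res.bmd / baseline.bmd)
        lr_bmdl = math.log10(res.bmdl / baseline.bmdl)
    else:
        lr_bmd = lr_bmdl = math.nan
    return ComparisonRow(
        method_id=spec.id,
        bmd=res.bmd,
        bmdl=res.bmdl,
        log10_bmd_ratio=lr_bmd,
        log10_bmdl_ratio=lr_bmdl,
        gof_p=fit.gof_p,
        converged=fit.converged,
        warnings=res.warnings,
    )


def compare_methods(
    study: LitterStudy,
    method_ids: Sequence[int] = tuple(range(1, 16)),
    confidence: float = 0.95,
    slope_min: float = 1.0,
) -> pd.DataFrame:
    """Run a set of methods against the NLL baseline; returns a tidy table
    (one row per method, plus a method-0 row for the baseline itself)."""
    _, base = fit_baseline_nll(study, confidence=confidence,
                               slope_min=slope_min)
    rows = [{
        "study": study.study_id, "method": 0, "label": "NLL baseline",
        "bmd": base.bmd, "bmdl": base.bmdl,
        "log10_bmd_ratio": 0.0, "log10_bmdl_ratio": 0.0,
        "gof_p": math.nan, "converged": True,
    }]
    for mid in method_ids:
        spec = METHOD_SPECS[mid]
        try:
            r = run_method(study, spec, baseline=base,
                           confidence=confidence, slope_min=slope_min)
            rows.append({
                "study": study.study_id, "method": mid, "label": spec.label,
                "bmd": r.bmd, "bmdl": r.bmdl,
                "log10_bmd_ratio": r.log10_bmd_ratio,
                "log10_bmdl_ratio": r.log10_bmdl_ratio,
                "gof_p": r.gof_p, "converged": r.converged,
            })
        except LitterBmdError as exc:
            rows.append({
                "study": study.study_id, "method": mid, "label": spec.label,
                "bmd": math.nan, "bmdl": math.nan,
                "log10_bmd_ratio": math.nan, "log10_bmdl_ratio": math.nan,
                "gof_p": math.nan, "converged": False, "error": str(exc),
            })
    return pd.DataFrame(rows)


def summarize_log_ratios(values: Iterable[float]) -> RatioSummary:
    """Mean, sample SD, and RMSE = sqrt(mean^2 + sd^2) of log10 ratios;
    non-finite values (nonconverged fits) are excluded."""
    v = np.asarray([x for x in values if math.isfinite(x)], dtype=float)
    if v.size == 0:
        raise InsufficientDataError("no finite ratios to summarize")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return RatioSummary(mean=mean, sd=sd, rmse=math.hypot(mean, sd), n=v.size)


def ratio_interval(sigma_log10: float, confidence: float = 0.95) -> tuple[float, float]:
    """If log10 ratios are normal with SD ``sigma_log10``, the two-sided
    ``confidence`` interval for the ratio itself: 10^(±z·sigma)."""
    z = stats.norm.ppf(0.5 + confidence / 2)
    return (10 ** (-z * sigma_log10), 10 ** (z * sigma_log10))
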