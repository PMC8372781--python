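"""Rao-Scott design effects: estimation, pooling, historical prediction,
and the transformation to effective counts.

The design effect D of a dose group is the ratio of the cluster-aware
variance of the proportion affected to the naive binomial variance
P_F(1-P_F)/N_F. With litter sizes ``n_i``, litter proportions ``p_i``, group
proportion ``P_F`` and ``m`` litters,

    Vhat = m/(m-1) * (1/N_F^2) * sum_i n_i^2 (p_i - P_F)^2
    D    = Vhat / [P_F (1-P_F) / N_F]

which for litters of size 1 gives exactly ``m/(m-1)`` (≈ 1, as independence
requires) and for equal litter sizes n tracks ``1 + (n-1)*rho`` with
intralitter correlation rho. Dividing both counts by D ("Rao-Scott
transformation") yields effective sample sizes N_F/D and A_F/D that behave
approximately binomially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .constants import HISTORICAL_DEFF_COEFFS
from .data_model import DoseGroup, GroupSummary, LitterStudy, summarize_group
from .errors import (
    DegenerateGroupError,
    FitError,
    InsufficientDataError,
    MissingCoefficientsError,
)


@dataclass(frozen=True)
class DesignEffect:
    """An estimated, predicted, or assumed design effect.

    ``value`` may fall below 1 (underdispersion happens in real groups) and
    is 0 when every litter proportion equals the group proportion; callers
    wanting a conservative floor can pass ``floor_at_one=True`` to the
    estimators. Transformation requires a strictly positive value.
    """

    value: float
    source: str  # group | pooled | historical | fixed
    group_dose: float | None = None

    def __post_init__(self) -> None:
        if not self.value >= 0:
            raise ValueError(
                f"design effect must be non-negative, got {self.value}")


@dataclass(frozen=True)
class HistoricalFit:
    """Log-log regression of design effect on proportion affected:
    ln D = a + b ln P_F, with residual variance on the ln scale."""

    species: str
    method: str  # LS | OR
    intercept: float
    slope: float
    resid_var: float
    n_groups: int

    def __post_init__(self) -> None:
        if self.resid_var < 0:
            raise ValueError("residual variance cannot be negative")

    def predict(self, p_fetal: float, mode: str = "mean") -> float:
        """Back-transformed design effect at ``p_fetal``.

        ``mode="mean"`` applies the lognormal mean correction
        exp(a + b ln P + resid_var/2); ``mode="median"`` omits it.
        """
        if not 0 < p_fetal <= 1:
            raise ValueError(f"p_fetal must be in (0, 1], got {p_fetal}")
        log_d = self.intercept + self.slope * math.log(p_fetal)
        if mode == "mean":
            log_d += 0.5 * self.resid_var
        elif mode != "median":
            raise ValueError(f"unknown mode {mode!r}")
        return math.exp(log_d)


@dataclass(frozen=True)
class TransformedGroup:
    """Effective counts after dividing by the design effect."""

    dose: float
    eff_n: float
    eff_a: float

    def __post_init__(self) -> None:
        if not self.eff_n > 0:
            raise ValueError("effective n must be positive")
        if not -1e-9 <= self.eff_a <= self.eff_n + 1e-9:
            raise ValueError("effective affected count outside [0, eff_n]")

    @property
    def proportion(self) -> float:
        return self.eff_a / self.eff_n


def _group_moments(group: DoseGroup) -> tuple[int, int, int, float, float]:
    """(m, N_F, A_F, P_F, weighted deviation sum sum n_i^2 (p_i-P_F)^2)."""
    sizes = np.array([r.size for r in group.litters], dtype=float)
    affected = np.array([r.affected for r in group.litters], dtype=float)
    n_f = sizes.sum()
    a_f = affected.sum()
    p_f = a_f / n_f
    dev = float(np.sum(sizes**2 * (affected / sizes - p_f) ** 2))
    return len(sizes), int(n_f), int(a_f), p_f, dev


def rao_scott_design_effect(
    group: DoseGroup, floor_at_one: bool = False
) -> DesignEffect:
    """Estimate the design effect of one dose group from its litters.

    Raises :class:`DegenerateGroupError` when P_F is 0 or 1 (the usual
    convention is then to substitute D = 1) and
    :class:`InsufficientDataError` with fewer than two litters.
    """
    m, n_f, _, p_f, dev = _group_moments(group)
    if m < 2:
        raise InsufficientDataError(
            f"dose group {group.dose}: need >= 2 litters to estimate D, got {m}"
        )
    if p_f <= 0 or p_f >= 1:
        raise DegenerateGroupError(
            f"dose group {group.dose}: P_F = {p_f:g}; design effect undefined "
            "(substitute D = 1 by convention)"
        )
    vhat_count = m / (m - 1) * dev  # = Vhat * N_F^2
    d = vhat_count / (n_f * p_f * (1 - p_f))
    if floor_at_one:
        d = max(d, 1.0)
    return DesignEffect(value=d, source="group", group_dose=group.dose)


def pooled_design_effect(
    study: LitterStudy,
    center: str = "group",
    floor_at_one: bool = False,
) -> DesignEffect:
    """Single design effect pooled over all dose groups of a study.

    ``center="group"`` (default) sums the per-group cluster-variance
    numerators and binomial-variance denominators (each group centered at its
    own P_F), so the dose effect is not absorbed into D. ``center="study"``
    pools all litters around the study-wide proportion instead.
    """
    if center == "study":
        all_litters = tuple(r for g in study.groups for r in g.litters)
        merged = DoseGroup(dose=all_litters[0].dose, litters=tuple(
            type(r)(r.study_id, r.species, all_litters[0].dose, r.litter_id,
                    r.size, r.affected)
            for r in all_litters
        ))
        d = rao_scott_design_effect(merged, floor_at_one=floor_at_one)
        return DesignEffect(value=d.value, source="pooled")

    num = 0.0
    den = 0.0
    for g in study.groups:
        m, n_f, _, p_f, dev = _group_moments(g)
        if m < 2 or p_f <= 0 or p_f >= 1:
            continue
        num += m / (m - 1) * dev
        den += n_f * p_f * (1 - p_f)
    if den == 0:
        raise InsufficientDataError(
            f"study {study.study_id!r}: no dose group with >= 2 litters and "
            "non-degenerate P_F"
        )
    d = num / den
    if floor_at_one:
        d = max(d, 1.0)
    return DesignEffect(value=d, source="pooled")


def orthogonal_line(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Orthogonal (total) least-squares line assuming equal error variances.

    Returns (intercept, slope) of the line minimizing summed squared
    perpendicular distances. Closed form:
    slope = [S_yy - S_xx + sqrt((S_yy - S_xx)^2 + 4 S_xy^2)] / (2 S_xy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    if sxy == 0:
        if syy <= sxx:
            slope = 0.0
        else:
            raise FitError("orthogonal fit degenerate: vertical line")
    else:
        slope = (syy - sxx + math.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
    intercept = y.mean() - slope * x.mean()
    return float(intercept), float(slope)


def fit_design_effect_regression(
    points: Iterable[tuple[float, float]],
    method: str = "LS",
    species: str = "other",
) -> HistoricalFit:
    """Fit ln D = a + b ln P_F to (P_F, D) pairs by LS or orthogonal (OR)
    regression; residual variance is that of vertical residuals about the
    fitted line with divisor n-2."""
    pts = [(p, d) for p, d in points]
    if len(pts) < 3:
        raise FitError(f"need >= 3 points to fit, got {len(pts)}")
    if any(p <= 0 or d <= 0 for p, d in pts):
        raise FitError("all P_F and D values must be strictly positive")
    x = np.log([p for p, _ in pts])
    y = np.log([d for _, d in pts])
    if np.allclose(x, x[0]):
        raise FitError("zero variance in log P_F; slope not identifiable")
    if method == "LS":
        res = sm.OLS(y, sm.add_constant(x)).fit()
        a, b = float(res.params[0]), float(res.params[1])
    elif method == "OR":
        a, b = orthogonal_line(x, y)
    else:
        raise ValueError(f"unknown method {method!r} (expected 'LS' or 'OR')")
    resid = y - (a + b * x)
    resid_var = float(np.sum(resid**2) / (len(pts) - 2))
    return HistoricalFit(
        species=species,
        method=method,
        intercept=a,
        slope=b,
        resid_var=resid_var,
        n_groups=len(pts),
    )


def shipped_historical_fits(species: str) -> dict[str, HistoricalFit]:
    """The built-in LS and OR historical fits for a species."""
    out = {}
    for meth in ("LS", "OR"):
        key = (species, meth)
        if key not in HISTORICAL_DEFF_COEFFS:
            raise MissingCoefficientsError(
                f"no shipped design-effect coefficients for species "
                f"{species!r}; supply a HistoricalFit"
            )
        a, b, s2, n = HISTORICAL_DEFF_COEFFS[key]
        out[meth] = HistoricalFit(species, meth, a, b, s2, n)
    return out


def predict_design_effect(
    species: str | None = None,
    p_fetal: float = 0.05,
    mode: str = "mean",
    combine: str = "average_LS_OR",
    fits: dict[str, HistoricalFit] | None = None,
    log_scale_average: bool = False,
) -> DesignEffect:
    """Predict the design effect D_h at a given P_F from historical fits.

    ``combine`` selects the LS prediction, the OR prediction, or their
    average (default); the average is taken on the natural D scale unless
    ``log_scale_average`` is set. ``fits`` overrides the shipped constants.
    """
    if fits is None:
        if species is None:
            raise MissingCoefficientsError("species or explicit fits required")
        fits = shipped_historical_fits(species)
    if combine in ("LS", "OR"):
        value = fits[combine].predict(p_fetal, mode=mode)
    elif combine == "average_LS_OR":
        d_ls = fits["LS"].predict(p_fetal, mode=mode)
        d_or = fits["OR"].predict(p_fetal, mode=mode)
        if log_scale_average:
            value = math.exp(0.5 * (math.log(d_ls) + math.log(d_or)))
        else:
            value = 0.5 * (d_ls + d_or)
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    return DesignEffect(value=value, source="historical")


def rao_scott_transform(
    summary: GroupSummary, d: DesignEffect | float, response: str = "p_fetal"
) -> TransformedGroup:
    """Divide a group's counts by its design effect.

    ``response`` chooses which proportion the effective affected count
    preserves: the ratio estimator ``p_fetal`` (default) or the litter-mean
    ``p_avg``. Counts are left fractional (no rounding).
    """
    d_val = d.value if isinstance(d, DesignEffect) else float(d)
    if not d_val > 0:
        raise ValueError("design effect must be positive")
    if response == "p_fetal":
        prop = summary.p_fetal
    elif response == "p_avg":
        prop = summary.p_avg
        if math.isnan(prop):
            raise ValueError("p_avg is not available for this group")
    else:
        raise ValueError(f"unknown response {response!r}")
    eff_n = summary.n_fetuses / d_val
    return TransformedGroup(dose=summary.dose, eff_n=eff_n, eff_a=prop * eff_n)


def group_design_effect_or_one(group: DoseGroup) -> DesignEffect:
    """Per-group D_g with the conventional D = 1 substitution for degenerate
    groups (P_F of 0 or 1) or single-litter groups."""
    try:
        return rao_scott_design_effect(group)
    except (DegenerateGroupError, InsufficientDataError):
        return DesignEffect(value=1.0, source="group", group_dose=group.dose)


def study_design_effects(study: LitterStudy) -> list[DesignEffect]:
    """Per-group design effects for a study (D = 1 where undefined)."""
    return [group_design_effect_or_one(g) for g in study.groups]
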