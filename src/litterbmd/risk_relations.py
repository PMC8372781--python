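"""Extra-risk arithmetic, litter-risk vs fetal-risk relations, and the
design-effect-adjusted Cochran-Armitage trend test.

The probability that a litter contains at least one affected fetus (P_L)
greatly exceeds the per-fetus probability (P_F): under independence and a
constant litter size n, P_L = 1 - (1 - P_F)^n. Empirically the relation is
close to log-linear for small P_F; shipped historical coefficients predict
P_L from P_F on the log10 scale.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from . import constants
from .data_model import GroupSummary
from .design_effect import DesignEffect, orthogonal_line
from .errors import FitError, InsufficientDataError


def extra_risk(p_x: float, p_0: float) -> float:
    """Extra risk (p_x - p_0)/(1 - p_0): the fraction of background-unaffected
    subjects that become affected at dose X. May be negative."""
    if not 0 <= p_0 < 1:
        raise ValueError("p_0 must be in [0, 1)")
    if not 0 <= p_x <= 1:
        raise ValueError("p_x must be in [0, 1]")
    return (p_x - p_0) / (1 - p_0)


@dataclass(frozen=True)
class PlPfRelation:
    """A relation mapping fetal proportion P_F to litter proportion P_L.

    Forms: ``independence`` (P_L = 1-(1-P_F)^n, coefficient n = litter
    size); ``loglinear`` (log10 P_L = c0 + c1 log10 P_F); ``quadratic``
    (adds c2 [log10 P_F]^2).
    """

    form: str
    coefficients: tuple[float, ...]

    def __call__(self, p_fetal: float) -> float:
        return litter_risk(p_fetal, self)


def litter_risk(p_fetal: float, relation: PlPfRelation) -> float:
    """Predicted proportion of affected litters at fetal proportion
    ``p_fetal``; values exceeding 1 are clipped with a warning."""
    if relation.form == "independence":
        if not 0 <= p_fetal <= 1:
            raise ValueError("p_fetal must be in [0, 1]")
        (n,) = relation.coefficients
        if n < 1:
            raise ValueError("litter size must be >= 1")
        return 1 - (1 - p_fetal) ** n
    if not 0 < p_fetal < 1:
        raise ValueError("p_fetal must be in (0, 1) for fitted relations")
    lx = math.log10(p_fetal)
    if relation.form == "loglinear":
        c0, c1 = relation.coefficients
        ly = c0 + c1 * lx
    elif relation.form == "quadratic":
        c0, c1, c2 = relation.coefficients
        ly = c0 + c1 * lx + c2 * lx**2
    else:
        raise ValueError(f"unknown relation form {relation.form!r}")
    p_l = 10**ly
    if p_l > 1:
        _warnings.warn(
            f"relation predicts P_L = {p_l:.3g} > 1 at P_F = {p_fetal:g}; "
            "clipping to 1", stacklevel=2)
        p_l = 1.0
    return p_l


def shipped_pl_pf_relations() -> dict[str, PlPfRelation]:
    """Historical P_L-vs-P_F relations shipped as constants."""
    return {
        "orthogonal": PlPfRelation("loglinear", constants.PL_PF_LOGLINEAR_OR),
        "ols": PlPfRelation("loglinear", constants.PL_PF_LOGLINEAR_LS),
        "quadratic": PlPfRelation("quadratic", constants.PL_PF_QUADRATIC_LS),
    }


def fit_pl_pf_relation(
    points: Iterable[tuple[float, float]],
    form: str = "loglinear",
    method: str = "LS",
) -> PlPfRelation:
    """Fit a log10-scale P_L-vs-P_F relation to (P_F, P_L) pairs.

    The quadratic form is available only with LS; orthogonal loglinear
    fitting reuses the total-least-squares line.
    """
    pts = [(pf, pl) for pf, pl in points]
    min_pts = 3 if form == "loglinear" else 4
    if len(pts) < min_pts:
        raise FitError(f"need >= {min_pts} points for the {form} form")
    if any(not (0 < pf < 1 and 0 < pl < 1) for pf, pl in pts):
        raise FitError("all P_F and P_L must be strictly inside (0, 1)")
    x = np.log10([pf for pf, _ in pts])
    y = np.log10([pl for _, pl in pts])
    if np.allclose(x, x[0]):
        raise FitError("zero spread in log10 P_F")
    if form == "loglinear":
        if method == "OR":
            c0, c1 = orthogonal_line(x, y)
        elif method == "LS":
            res = sm.OLS(y, sm.add_constant(x)).fit()
            c0, c1 = float(res.params[0]), float(res.params[1])
        else:
            raise ValueError(f"unknown method {method!r}")
        return PlPfRelation("loglinear", (c0, c1))
    if form == "quadratic":
        if method != "LS":
            raise ValueError("quadratic form is fit by LS only")
        X = sm.add_constant(np.column_stack([x, x**2]))
        res = sm.OLS(y, X).fit()
        return PlPfRelation("quadratic", tuple(float(v) for v in res.params))
    raise ValueError(f"unknown form {form!r}")


@dataclass(frozen=True)
class TrendTestResult:
    statistic: float
    p_one_sided: float
    p_two_sided: float
    adjusted: bool
    design_effects_used: tuple[float, ...]


def adjusted_trend_test(
    summaries: Sequence[GroupSummary],
    design_effects: Sequence[DesignEffect | float] | None = None,
    scores: Sequence[float] | None = None,
    use_ranks: bool = False,
) -> TrendTestResult:
    """Cochran-Armitage trend test on counts divided by per-group design
    effects (Rao-Scott adjustment for intralitter correlation).

    With all design effects equal to 1 this is exactly the classical test.
    The one-sided p-value is for an increasing trend; dose scores default to
    the literal dose values (``use_ranks=True`` substitutes rank scores).
    """
    if len(summaries) < 2:
        raise InsufficientDataError("need >= 2 dose groups")
    if design_effects is None:
        dvals = np.ones(len(summaries))
    else:
        dvals = np.array([
            d.value if isinstance(d, DesignEffect) else float(d)
            for d in design_effects
        ])
        if len(dvals) != len(summaries):
            raise ValueError("one design effect per group required")
        if np.any(dvals <= 0):
            raise ValueError("design effects must be positive")
    if scores is None:
        scores = [s.dose for s in summaries]
    s = (stats.rankdata(scores) if use_ranks
         else np.asarray(scores, dtype=float))
    n = np.array([g.n_fetuses for g in summaries], float) / dvals
    a = np.array([g.n_affected for g in summaries], float) / dvals
    n_tot = n.sum()
    pbar = a.sum() / n_tot
    if pbar <= 0 or pbar >= 1:
        raise InsufficientDataError(
            "pooled proportion is 0 or 1; trend statistic undefined")
    num = float(np.sum(s * (a - n * pbar)))
    den = pbar * (1 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / n_tot)
    if den <= 0:
        raise InsufficientDataError("zero score variance; statistic undefined")
    z = num / math.sqrt(den)
    return TrendTestResult(
        statistic=z,
        p_one_sided=float(stats.norm.sf(z)),
        p_two_sided=float(2 * stats.norm.sf(abs(z))),
        adjusted=design_effects is not None,
        design_effects_used=tuple(float(v) for v in dvals),
    )
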