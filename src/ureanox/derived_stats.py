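"""Derived statistics: N₂O yields, substrate fractions, rate ratios,
treatment comparisons.

Yields are computed on an N-atom basis by default: the N₂O rate (nmol
N₂O L⁻¹ d⁻¹) carries two N atoms per molecule, so it is doubled before
being compared with the nitrite rate (nmol N L⁻¹ d⁻¹).  A ``molecule``
basis is available for audit since field reports rarely state which was
used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy import stats

from .rate_estimation import RateEstimate

__all__ = [
    "YieldEstimate",
    "RatioEstimate",
    "TreatmentComparison",
    "yield_percent",
    "n2o_yield",
    "rate_ratio",
    "urea_to_N",
    "substrate_fraction",
    "compare_treatments",
]


@dataclass(frozen=True)
class YieldEstimate:
    """N₂O yield as a percentage of total oxidised N, with propagated SE."""

    percent: float
    se: float


@dataclass(frozen=True)
class RatioEstimate:
    """A ratio of two rates with first-order propagated uncertainty."""

    value: float
    sigma: float
    numerator_below_dl: bool = False
    denominator_below_dl: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class TreatmentComparison:
    """Welch t-test between two rate estimates plus the relative change."""

    t_statistic: float
    df: float
    p_value: float
    percent_change: float


def yield_percent(n2o_N: float, no2_N: float, se_n2o: float = 0.0, se_no2: float = 0.0) -> YieldEstimate:
    """yield% = 100·a/(a+b) with first-order error propagation.

    Both inputs must already be on the same N-atom basis.
    ∂y/∂a = 100·b/(a+b)², ∂y/∂b = −100·a/(a+b)².
    """
    total = n2o_N + no2_N
    if total <= 0.0:
        raise ZeroDivisionError("yield undefined: n2o + no2 rate sum must be > 0")
    pct = 100.0 * n2o_N / total
    se = 100.0 / total**2 * math.hypot(no2_N * se_n2o, n2o_N * se_no2)
    return YieldEstimate(percent=pct, se=se)


def n2o_yield(
    n2o: RateEstimate,
    no2: RateEstimate,
    basis: Literal["N", "molecule"] = "N",
) -> YieldEstimate:
    """N₂O yield of an oxidation pathway: N₂O / (N₂O + nitrite) · 100.

    Under the default ``"N"`` basis a rate tagged ``product="n2o"`` is
    multiplied by 2 (two N atoms per molecule) before forming the ratio.
    """
    scale = 2.0 if (basis == "N" and n2o.product == "n2o") else 1.0
    return yield_percent(
        scale * n2o.value, no2.value, scale * n2o.se, no2.se
    )


def rate_ratio(numer: RateEstimate, denom: RateEstimate) -> RatioEstimate:
    """Quotient of two rates with the standard error-propagation rule.

    sigma = |r|·sqrt((σa/a)² + (σb/b)²); a zero numerator degrades
    gracefully to sigma = σa/|b|.  Below-detection flags ride along.
    """
    if denom.value == 0.0:
        raise ZeroDivisionError("denominator rate is zero")
    value = numer.value / denom.value
    if numer.value == 0.0:
        sigma = numer.se / abs(denom.value)
    else:
        sigma = abs(value) * math.hypot(
            numer.se / numer.value, denom.se / denom.value
        )
    return RatioEstimate(
        value=value,
        sigma=sigma,
        numerator_below_dl=numer.below_detection,
        denominator_below_dl=denom.below_detection,
    )


def urea_to_N(urea_molar: float) -> float:
    """Convert µmol urea L⁻¹ to µmol N L⁻¹ (urea carries two N atoms)."""
    if urea_molar < 0:
        raise ValueError("urea concentration must be >= 0")
    return 2.0 * urea_molar


def substrate_fraction(urea_N: float, nh4: float) -> float:
    """Fraction of urea-N in the combined ammonium + urea-N pool."""
    total = urea_N + nh4
    if total <= 0.0:
        raise ZeroDivisionError("substrate fraction undefined for zero total pool")
    return urea_N / total


def compare_treatments(a: RateEstimate, b: RateEstimate) -> TreatmentComparison:
    """Welch two-sample t-test on two slope-derived rate estimates.

    ``a`` is the treated estimate, ``b`` the reference (in-situ) one;
    percent_change = 100·(a−b)/b.  Degrees of freedom come from each
    estimate's underlying slope fit via the Welch–Satterthwaite formula.
    """
    for est in (a, b):
        if not math.isfinite(est.se) or est.se < 0:
            raise ValueError("both estimates need finite standard errors")
        if est.df < 1:
            raise ValueError("both estimates need >= 1 residual df")
    pooled_var = a.se**2 + b.se**2
    if pooled_var == 0.0:
        t = 0.0 if a.value == b.value else math.inf
        df = float(a.df + b.df)
    else:
        t = (a.value - b.value) / math.sqrt(pooled_var)
        df = pooled_var**2 / (a.se**4 / a.df + b.se**4 / b.df)
    p = float(2.0 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    if b.value == 0.0:
        raise ZeroDivisionError("reference rate is zero; percent change undefined")
    return TreatmentComparison(
        t_statistic=float(t),
        df=float(df),
        p_value=p,
        percent_change=100.0 * (a.value - b.value) / b.value,
    )
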