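"""Rate estimation from replicated incubation time courses.

Nitrite production is tracked as ¹⁵NO₂⁻ accumulation; N₂O production as
the progressive increase of mass-45 and mass-46 N₂O.  Both series are fit
by ordinary least squares over *all* bottles (duplicates enter as
independent observations, not averaged per time point), the slope is
converted from per-hour to per-day, and the tracer-dilution correction
divides by the pool label fraction F (nitrite) or 2F (N₂O ¹⁵N-atom
excess).

Detection limits follow the minimal-detectable-slope logic: the smallest
rate whose fitted slope exceeds the one-sided t-quantile of the null
(zero-slope) slope standard error for the given design and measurement
noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracer_core import SubstratePool, label_fraction

__all__ = [
    "TimeCourse",
    "SlopeFit",
    "RateEstimate",
    "fit_time_course",
    "nitrite_production_rate",
    "n2o_production_rate",
    "detection_limit",
    "InsufficientDesignError",
    "LOW_LABEL_FLOOR",
]

HOURS_PER_DAY = 24.0

#: Below this pool label fraction, rate inversion amplifies noise by > 100×;
#: estimates are flagged rather than refused.
LOW_LABEL_FLOOR = 0.01

_TREATMENTS = ("in_situ", "plus_ammonium", "plus_urea")

POINT_COLUMNS = ["time_h", "replicate_id", "n2o44", "n2o45", "n2o46", "no2_15N"]


class InsufficientDesignError(ValueError):
    """Raised when a time course has too few distinct time points to fit."""


@dataclass
class TimeCourse:
    """One incubation: replicated isotopologue measurements over time.

    ``points`` is a DataFrame with columns ``time_h, replicate_id, n2o44,
    n2o45, n2o46, no2_15N`` (N₂O isotopologues in nmol L⁻¹, ¹⁵NO₂⁻ in
    nmol N L⁻¹).  The ¹⁵NO₂⁻ column is an excess over natural abundance
    and may be slightly negative after calibration; raw isotopologue
    concentrations must be ≥ 0.
    """

    station: str
    depth: float
    substrate: str
    treatment: str
    pool: SubstratePool
    points: pd.DataFrame

    def __post_init__(self) -> None:
        if self.treatment not in _TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.substrate != self.pool.species:
            raise ValueError("time-course substrate must match its pool species")
        missing = [c for c in POINT_COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"points missing columns: {missing}")
        pts = self.points
        if (pts["time_h"] < 0).any():
            raise ValueError("incubation times must be >= 0")
        for col in ("n2o44", "n2o45", "n2o46"):
            if (pts[col] < 0).any():
                raise ValueError(f"negative concentration in column {col}")
        n_times = pts["time_h"].nunique()
        if n_times < 2:
            raise InsufficientDesignError(
                "need >= 2 distinct incubation times to define a slope"
            )
        if n_times < 3:
            warnings.warn(
                f"time course {self.station}/{self.substrate} has only "
                f"{n_times} distinct time points; slope SE will be fragile",
                stacklevel=2,
            )

    @property
    def label_fraction(self) -> float:
        return label_fraction(self.pool)


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope of a concentration series on time, reported per day."""

    slope: float
    slope_se: float
    intercept: float
    r2: float
    p_value: float
    n: int

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class RateEstimate:
    """A gross production rate with SE, detection limit and flags.

    ``value`` is nmol N L⁻¹ d⁻¹ for nitrite, nmol N₂O L⁻¹ d⁻¹ for N₂O.
    Negative fitted slopes are retained (not truncated) and flagged below
    detection so that downstream ratio statistics stay unbiased.
    """

    value: float
    se: float
    detection_limit: float
    below_detection: bool
    product: Literal["nitrite", "n2o"]
    substrate: str
    df: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.detection_limit < 0:
            raise ValueError("detection limit must be >= 0")

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval on the rate."""
        if self.df < 1:
            return (-np.inf, np.inf)
        half = stats.t.ppf(0.5 + level / 2.0, self.df) * self.se
        return (self.value - half, self.value + half)


def _series_values(tc: TimeCourse, tracer_series: str) -> np.ndarray:
    if tracer_series == "no2_15N":
        return tc.points["no2_15N"].to_numpy(dtype=float)
    if tracer_series == "n2o_excess":
        # ¹⁵N-atom excess per litre: one atom per mass-45, two per mass-46.
        return (tc.points["n2o45"] + 2.0 * tc.points["n2o46"]).to_numpy(dtype=float)
    raise ValueError(f"unknown tracer series {tracer_series!r}")


def fit_time_course(
    tc: TimeCourse, tracer_series: Literal["no2_15N", "n2o_excess"]
) -> SlopeFit:
    """OLS of a tracer series on time, pooling all bottles, slope per day."""
    y = _series_values(tc, tracer_series)
    t_days = tc.points["time_h"].to_numpy(dtype=float) / HOURS_PER_DAY
    if np.unique(t_days).size < 2:
        raise InsufficientDesignError("need >= 2 distinct incubation times")
    res = stats.linregress(t_days, y)
    n = len(y)
    se = float(res.stderr) if n >= 3 else float("inf")
    return SlopeFit(
        slope=float(res.slope),
        slope_se=se,
        intercept=float(res.intercept),
        r2=float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0,
        p_value=float(res.pvalue),
        n=n,
    )


def _check_label(F: float) -> tuple[str, ...]:
    if F <= 0.0:
        raise ZeroDivisionError("pool label fraction F must be > 0")
    if F < LOW_LABEL_FLOOR:
        warnings.warn(
            f"pool label fraction F={F:.4g} below floor {LOW_LABEL_FLOOR}; "
            "rate inversion strongly amplifies noise",
            stacklevel=3,
        )
        return ("low_label_fraction",)
    return ()


def _estimate(
    fit: SlopeFit,
    divisor: float,
    dl: float,
    product: Literal["nitrite", "n2o"],
    substrate: str,
    flags: tuple[str, ...],
) -> RateEstimate:
    value = fit.slope / divisor
    return RateEstimate(
        value=value,
        se=fit.slope_se / divisor,
        detection_limit=dl,
        below_detection=value < dl,
        product=product,
        substrate=substrate,
        df=fit.df,
        flags=flags,
    )


def nitrite_production_rate(
    tc: TimeCourse,
    noise_sd: float | None = None,
    alpha: float = 0.05,
    dilution_correction: Literal["divide", "multiply"] = "divide",
) -> RateEstimate:
    """Gross nitrite production rate from the ¹⁵NO₂⁻ series.

    rate = slope(¹⁵NO₂⁻)/F in nmol N L⁻¹ d⁻¹.  ``dilution_correction``
    exists only for auditing the (dimensionally inconsistent)
    multiply-by-F variant; leave it at ``"divide"``.

    ``noise_sd`` (nmol N L⁻¹, per-bottle measurement SD) fixes the
    detection limit; if omitted, the fit's own residual noise is used.
    """
    F = tc.label_fraction
    flags = _check_label(F)
    fit = fit_time_course(tc, "no2_15N")
    divisor = F if dilution_correction == "divide" else 1.0 / F
    dl = _dl_from_design(tc, noise_sd, fit, F, alpha, n_atoms=1)
    return _estimate(fit, divisor, dl, "nitrite", tc.substrate, flags)


def n2o_production_rate(
    tc: TimeCourse,
    noise_sd: float | None = None,
    alpha: float = 0.05,
) -> RateEstimate:
    """Gross N₂O production rate from the mass-45/46 excess series.

    The pooled ¹⁵N-atom excess slope (s45 + 2·s46, obtained in one fit
    because OLS is linear) is divided by 2F; units nmol N₂O L⁻¹ d⁻¹.
    """
    F = tc.label_fraction
    flags = _check_label(F)
    fit = fit_time_course(tc, "n2o_excess")
    dl = _dl_from_design(tc, noise_sd, fit, F, alpha, n_atoms=2)
    return _estimate(fit, 2.0 * F, dl, "n2o", tc.substrate, flags)


def _null_slope_se(times_d: np.ndarray, noise_sd: float) -> float:
    """Closed-form OLS slope SE under pure iid Gaussian noise."""
    sxx = float(np.sum((times_d - times_d.mean()) ** 2))
    if sxx <= 0.0:
        raise InsufficientDesignError("degenerate design: all times equal")
    return noise_sd / np.sqrt(sxx)


def _dl_from_design(
    tc: TimeCourse,
    noise_sd: float | None,
    fit: SlopeFit,
    F: float,
    alpha: float,
    n_atoms: int,
) -> float:
    times = tc.points["time_h"].to_numpy(dtype=float)
    if noise_sd is None:
        # fall back on the fit's own residual scale: slope_se already equals
        # sigma_hat / sqrt(Sxx)
        se0 = fit.slope_se if np.isfinite(fit.slope_se) else 0.0
    else:
        se0 = _null_slope_se(times / HOURS_PER_DAY, noise_sd)
    df = max(len(times) - 2, 1)
    return float(stats.t.ppf(1.0 - alpha, df) * se0 / (n_atoms * F))


def detection_limit(
    times_h: Sequence[float],
    replicates: int,
    noise_sd: float,
    F: float,
    alpha: float = 0.05,
    product: Literal["nitrite", "n2o"] = "nitrite",
) -> float:
    """Minimal detectable rate for a given incubation design.

    DL = t(1−α, df) · SE₀(slope) / F  (nitrite, noise on ¹⁵NO₂⁻) or
    DL = t(1−α, df) · SE₀(slope) / (2F)  (N₂O, noise on the atom-excess
    series), with SE₀ the OLS slope standard error under pure noise of SD
    ``noise_sd`` for the stated design.  One-sided, default α = 0.05.
    """
    times = np.asarray(times_h, dtype=float)
    if times.size < 3 or replicates < 1:
        raise InsufficientDesignError("need >= 3 time points and >= 1 replicate")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if F <= 0.0:
        raise ZeroDivisionError("F must be > 0")
    design = np.repeat(times / HOURS_PER_DAY, replicates)
    se0 = _null_slope_se(design, noise_sd)
    df = design.size - 2
    n_atoms = 1 if product == "nitrite" else 2
    return float(stats.t.ppf(1.0 - alpha, df) * se0 / (n_atoms * F))


def rates_table(time_courses: Iterable[TimeCourse], **kwargs) -> pd.DataFrame:
    """Estimate nitrite and N₂O rates for many incubations.

    Returns one row per (station, depth, substrate, treatment, product).
    """
    rows = []
    for tc in time_courses:
        for product, est in (
            ("nitrite", nitrite_production_rate(tc, **kwargs)),
            ("n2o", n2o_production_rate(tc, **kwargs)),
        ):
            rows.append(
                {
                    "station": tc.station,
                    "depth_m": tc.depth,
                    "substrate": tc.substrate,
                    "treatment": tc.treatment,
                    "product": product,
                    "rate": est.value,
                    "se": est.se,
                    "df": est.df,
                    "detection_limit": est.detection_limit,
                    "below_detection": est.below_detection,
                    "label_fraction": tc.label_fraction,
                }
            )
    return pd.DataFrame(rows)
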