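"""Isotope bookkeeping for ¹⁵N tracer incubations.

A tracer experiment spikes an ammonium or urea pool with highly enriched
¹⁵N substrate.  Everything downstream (rate inversion, detection limits)
hinges on two quantities computed here:

* ``F`` — the ¹⁵N atom fraction of the spiked substrate pool, the
  concentration-weighted mean of the ambient and tracer atom fractions.
* the binomial distribution of N₂O isotopologues (m/z 44, 45, 46 for
  molecules carrying 0, 1 or 2 ¹⁵N atoms) produced from that pool, under
  the assumption that both N atoms of a product N₂O molecule are drawn
  independently from the same labelled substrate pool.

The binomial model is exactly invertible: the ¹⁵N-atom excess accumulation
rate (1·[45] + 2·[46]) equals ``2·F·R`` for gross N₂O production ``R``, so
``R = (s45 + 2·s46) / (2F)`` for the fitted isotopologue slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "NATURAL_ABUNDANCE_15N",
    "SubstratePool",
    "IsotopologueVector",
    "label_fraction",
    "isotopologue_fractions",
    "excess_to_n2o_rate",
    "forward_isotopologue_rates",
]

#: Atom fraction of ¹⁵N at natural abundance (air N₂ reference).
NATURAL_ABUNDANCE_15N = 0.003663

_SPECIES = ("ammonium", "urea")


class UndefinedPoolError(ValueError):
    """Raised when a substrate pool has zero total concentration."""


@dataclass(frozen=True)
class SubstratePool:
    """An ammonium or urea-N pool with ambient and tracer fractions.

    Concentrations are µmol N L⁻¹ throughout; urea must already be
    expressed in N units (2 × molar urea, see
    :func:`ureanox.derived_stats.urea_to_N`).

    Parameters
    ----------
    species : {"ammonium", "urea"}
    ambient_conc : float
        In-situ (unspiked) pool, µmol N L⁻¹.
    tracer_conc : float
        Added tracer, µmol N L⁻¹; field practice targets ~10 % of ambient.
    ambient_atom_frac15 : float
        ¹⁵N atom fraction of the ambient pool; defaults to natural abundance.
    tracer_atom_frac15 : float
        ¹⁵N atom fraction of the tracer (commercial spikes are ≥ 0.98).
    """

    species: str
    ambient_conc: float
    tracer_conc: float
    ambient_atom_frac15: float = NATURAL_ABUNDANCE_15N
    tracer_atom_frac15: float = 0.99

    def __post_init__(self) -> None:
        if self.species not in _SPECIES:
            raise ValueError(f"unknown substrate species {self.species!r}")
        if self.ambient_conc < 0 or self.tracer_conc < 0:
            raise ValueError("pool concentrations must be >= 0")
        for name in ("ambient_atom_frac15", "tracer_atom_frac15"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def total_conc(self) -> float:
        return self.ambient_conc + self.tracer_conc


@dataclass(frozen=True)
class IsotopologueVector:
    """Fractions of N₂O molecules carrying 0, 1 or 2 ¹⁵N atoms."""

    p44: float
    p45: float
    p46: float

    def __post_init__(self) -> None:
        for name in ("p44", "p45", "p46"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.p44 + self.p45 + self.p46 - 1.0) > 1e-12:
            raise ValueError("isotopologue fractions must sum to 1")


def label_fraction(pool: SubstratePool) -> float:
    """¹⁵N atom fraction ``F`` of the spiked substrate pool.

    F = (C_amb·a_amb + C_tr·a_tr) / (C_amb + C_tr): the fraction of all N
    atoms in the initial pool that are ¹⁵N.  Dividing labelled-product
    accumulation slopes by F converts them to gross rates.
    """
    total = pool.total_conc
    if total <= 0.0:
        raise UndefinedPoolError("ambient + tracer concentration must be > 0")
    return (
        pool.ambient_conc * pool.ambient_atom_frac15
        + pool.tracer_conc * pool.tracer_atom_frac15
    ) / total


def isotopologue_fractions(F: float) -> IsotopologueVector:
    """Binomial N₂O isotopologue distribution for pool label fraction ``F``.

    Both N atoms drawn independently from a pool with ¹⁵N fraction F:
    p44 = (1−F)², p45 = 2F(1−F), p46 = F².
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"label fraction F={F} outside [0, 1]")
    q = 1.0 - F
    return IsotopologueVector(p44=q * q, p45=2.0 * F * q, p46=F * F)


def excess_to_n2o_rate(slope45: float, slope46: float, F: float) -> float:
    """Invert isotopologue accumulation slopes to a gross N₂O production rate.

    ``rate = (slope45 + 2·slope46) / (2F)`` in nmol N₂O L⁻¹ d⁻¹.  The
    numerator is the ¹⁵N-atom excess accumulation rate, which under the
    binomial forward model equals ``2·F·R`` exactly for any F in (0, 1].
    Slopes may be negative (measurement noise); the inversion is linear.
    """
    if F <= 0.0:
        raise ZeroDivisionError("label fraction F must be > 0 to invert rates")
    if not (math.isfinite(slope45) and math.isfinite(slope46)):
        raise ValueError("isotopologue slopes must be finite")
    return (slope45 + 2.0 * slope46) / (2.0 * F)


def forward_isotopologue_rates(rate: float, F: float) -> tuple[float, float, float]:
    """Forward model: per-isotopologue accumulation rates for gross rate ``R``.

    Returns (d44/dt, d45/dt, d46/dt) in nmol N₂O L⁻¹ d⁻¹.  Used by the
    synthetic generator and by round-trip tests of :func:`excess_to_n2o_rate`.
    """
    if rate < 0:
        raise ValueError("gross production rate must be >= 0")
    p = isotopologue_fractions(F)
    return rate * p.p44, rate * p.p45, rate * p.p46
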