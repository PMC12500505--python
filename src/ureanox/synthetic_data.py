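"""Seeded generators emulating every input the analysis consumes.

The generators mirror the structure of a coastal-ocean tracer study:

* duplicate-bottle incubations at 0/4/8/12 h with the tracer at ~10 % of
  the ambient pool, ¹⁵NO₂⁻ accumulating at ``rate·F·t`` and N₂O
  isotopologues following the binomial forward model, plus Gaussian
  concentration noise (N₂O precision 0.33 nM);
* substrate-manipulation experiments (+2 µM ammonium or +18 µM N-urea)
  in which added ammonium suppresses urea oxidation;
* a global compilation of paired substrate concentrations and oxidation
  rates whose rate ratio follows a power law of the substrate ratio,
  with a polar-ocean regime sitting ~1 decade above the global line;
* per-gene coverage tables whose ureC:amoA ratio follows a linear
  relation to the substrate ratio, with Poisson coverage sampling.

All generators are pure functions of (config, seed): the same call
returns bit-identical output.  Randomness flows from one seed through
named integer substreams, one per generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .crosssite_regression import SiteRecord
from .gene_ratio import GeneCoverageRecord
from .rate_estimation import HOURS_PER_DAY, TimeCourse
from .tracer_core import (
    NATURAL_ABUNDANCE_15N,
    SubstratePool,
    isotopologue_fractions,
    label_fraction,
)

__all__ = [
    "SimConfig",
    "HABITAT_WEIGHTS",
    "HABITAT_LOG10_SUBSTRATE_RATIO",
    "HABITAT_NH4_MEDIAN",
    "F_RANGES",
    "simulate_incubation",
    "simulate_manipulation",
    "simulate_global_dataset",
    "simulate_coverage_table",
    "tracer_conc_for_F",
]

#: Observed label-fraction ranges the generator must stay inside.
F_RANGES = {"ammonium": (0.085, 0.372), "urea": (0.061, 0.180)}

#: Habitat composition of the synthetic global compilation (polar sites
#: are drawn separately at the configured outlier fraction).
HABITAT_WEIGHTS = {"estuary": 0.20, "coastal": 0.25, "open_ocean": 0.35, "omz": 0.10}

#: log10 of the urea-N : ammonium concentration ratio, (mean, sd) per
#: habitat.  Chosen so the pooled log10-ratio SD is ~0.37, which with the
#: default power-law scatter reproduces a field-like R² ≈ 0.66.
HABITAT_LOG10_SUBSTRATE_RATIO = {
    "estuary": (-0.6, 0.25),
    "coastal": (-0.3, 0.25),
    "open_ocean": (0.1, 0.25),
    "omz": (0.0, 0.25),
    "polar": (-0.5, 0.25),
}

#: Median ambient ammonium (µM) per habitat; eutrophic estuaries high,
#: oligotrophic gyres low.
HABITAT_NH4_MEDIAN = {
    "estuary": 2.0,
    "coastal": 0.5,
    "open_ocean": 0.05,
    "omz": 0.1,
    "polar": 0.5,
}

_COVERAGE_REGIONS = (
    "Chesapeake Bay",
    "Gulf of Mexico",
    "Equatorial Pacific",
    "ETNP OMZ",
    "ETSP OMZ",
    "North Pacific Subtropical Gyre",
)

# substream ids; a generator's rng is default_rng([seed, stream]).
_STREAMS = {"incubation": 1, "manipulation": 2, "global": 3, "coverage": 4}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with field-anchored defaults.

    Defaults encode the study conditions: 0/4/8/12 h duplicate bottles,
    0.33 nM N₂O concentration precision, label fractions inside the
    observed ranges, power-law coupling (slope 1.113, intercept −0.97,
    log10 scatter 0.3), ~5 % polar outliers one decade high, ammonium
    inhibition of urea oxidation (multiplier 0.4 ⇒ 60 % decrease), and a
    gene-ratio line of 0.083·x − 0.018.
    """

    seed: int = 0
    time_grid: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0)
    replicates: int = 2
    n2o_noise_sd: float = 0.33  # nM, N₂O concentration precision
    no2_noise_sd: float = 0.005  # nmol N L⁻¹ on the ¹⁵NO₂⁻ excess series
    #: "concentration": Gaussian noise of n2o_noise_sd on every isotopologue
    #: (concentration-level precision applied throughout).
    #: "ratio": n2o_noise_sd on the mass-44 (bulk) concentration only, with
    #: isotope-ratio-level noise of n2o_ratio_precision (relative, ~per-mil)
    #: on the 45/46 channels — how an isotope-ratio MS actually performs,
    #: and what makes sub-nmol N₂O production rates detectable.
    noise_mode: Literal["concentration", "ratio"] = "concentration"
    n2o_ratio_precision: float = 1e-3
    true_rates: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"ammonium": (50.0, 0.04), "urea": (5.0, 0.005)}
    )
    F_targets: Mapping[str, float] = field(
        default_factory=lambda: {"ammonium": 0.20, "urea": 0.12}
    )
    ambient_pools: Mapping[str, float] = field(
        default_factory=lambda: {"ammonium": 1.0, "urea": 1.0}
    )
    # CB2-like mid-depth pools used by the manipulation simulator (µM N)
    manipulation_pools: Mapping[str, float] = field(
        default_factory=lambda: {"ammonium": 0.17, "urea": 1.12}
    )
    n2o_background: float = 10.0  # nM ambient N₂O at natural abundance
    global_slope: float = 1.113
    global_intercept: float = -0.97
    scatter_log10: float = 0.3
    outlier_fraction: float = 0.05
    polar_shift_log10: float = 1.0
    inhibition_factor: float = 0.4
    nh4_addition: float = 2.0  # µM
    urea_addition: float = 18.0  # µM N
    generatio_slope: float = 0.083
    generatio_intercept: float = -0.018

    def __post_init__(self) -> None:
        if self.replicates < 1 or len(self.time_grid) < 2:
            raise ValueError("need >= 2 time points and >= 1 replicate")
        if self.noise_mode not in ("concentration", "ratio"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        for name in ("n2o_noise_sd", "no2_noise_sd", "scatter_log10", "n2o_ratio_precision"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for frac in ("outlier_fraction", "inhibition_factor"):
            if not 0.0 <= getattr(self, frac) <= 1.0:
                raise ValueError(f"{frac} must lie in [0, 1]")
        for species, F in self.F_targets.items():
            lo, hi = F_RANGES[species]
            if not lo <= F <= hi:
                raise ValueError(
                    f"F target {F} for {species} outside observed range [{lo}, {hi}]"
                )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def n2o_excess_noise_sd(self) -> float:
        """Per-bottle noise SD of the ¹⁵N-atom excess series (45 + 2·46).

        Both channels carry independent noise σ, so the combined series has
        SD σ·√(1+4).  In ratio mode σ is the relative ratio precision
        referenced to the ambient mass-45 signal.
        """
        if self.noise_mode == "ratio":
            bg45 = self.n2o_background * isotopologue_fractions(NATURAL_ABUNDANCE_15N).p45
            sigma = self.n2o_ratio_precision * bg45
        else:
            sigma = self.n2o_noise_sd
        return float(np.sqrt(5.0) * sigma)


def tracer_conc_for_F(
    ambient_conc: float,
    F: float,
    ambient_atom_frac15: float = NATURAL_ABUNDANCE_15N,
    tracer_atom_frac15: float = 0.99,
) -> float:
    """Tracer concentration that sets the pool label fraction to ``F``."""
    if not ambient_atom_frac15 < F < tracer_atom_frac15:
        raise ValueError("target F must lie between ambient and tracer fractions")
    return ambient_conc * (F - ambient_atom_frac15) / (tracer_atom_frac15 - F)


def _pool_for(cfg: SimConfig, substrate: str, ambient: float | None = None) -> SubstratePool:
    amb = cfg.ambient_pools[substrate] if ambient is None else ambient
    tracer = tracer_conc_for_F(amb, cfg.F_targets[substrate])
    return SubstratePool(species=substrate, ambient_conc=amb, tracer_conc=tracer)


def _simulate_points(
    cfg: SimConfig,
    pool: SubstratePool,
    nitrite_rate: float,
    n2o_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Forward-simulate one incubation's bottle measurements."""
    F = label_fraction(pool)
    p = isotopologue_fractions(F)
    p_bg = isotopologue_fractions(NATURAL_ABUNDANCE_15N)
    rows = []
    for t_h in cfg.time_grid:
        t_d = t_h / HOURS_PER_DAY
        produced = n2o_rate * t_d  # nmol N₂O L⁻¹
        true44 = cfg.n2o_background * p_bg.p44 + produced * p.p44
        true45 = cfg.n2o_background * p_bg.p45 + produced * p.p45
        true46 = cfg.n2o_background * p_bg.p46 + produced * p.p46
        true_no2 = nitrite_rate * F * t_d  # nmol ¹⁵N L⁻¹
        for rep in range(1, cfg.replicates + 1):
            if cfg.noise_mode == "ratio":
                # bulk concentration noise on mass 44; ratio-level (relative)
                # noise on the minor-isotopologue channels, referenced to the
                # mass-45 signal
                n44 = true44 + (rng.normal(0.0, cfg.n2o_noise_sd) if cfg.n2o_noise_sd > 0 else 0.0)
                sd_minor = cfg.n2o_ratio_precision * true45
                if sd_minor > 0:
                    n45 = true45 + rng.normal(0.0, sd_minor)
                    n46 = true46 + rng.normal(0.0, sd_minor)
                else:
                    n45, n46 = true45, true46
            elif cfg.n2o_noise_sd > 0:
                n44, n45, n46 = rng.normal([true44, true45, true46], cfg.n2o_noise_sd)
            else:
                n44, n45, n46 = true44, true45, true46
            no2 = true_no2 + (rng.normal(0.0, cfg.no2_noise_sd) if cfg.no2_noise_sd > 0 else 0.0)
            rows.append(
                {
                    "time_h": t_h,
                    "replicate_id": f"b{rep}",
                    # raw isotopologue concentrations cannot be negative
                    "n2o44": max(n44, 0.0),
                    "n2o45": max(n45, 0.0),
                    "n2o46": max(n46, 0.0),
                    "no2_15N": no2,
                }
            )
    return pd.DataFrame(rows, columns=["time_h", "replicate_id", "n2o44", "n2o45", "n2o46", "no2_15N"])


def simulate_incubation(
    cfg: SimConfig,
    station: str = "SYN1",
    depth: float = 10.0,
    substrate: Literal["ammonium", "urea"] = "ammonium",
    treatment: str = "in_situ",
    rng: np.random.Generator | None = None,
) -> TimeCourse:
    """One duplicate-bottle tracer incubation at the configured true rates.

    Deterministic per (cfg, arguments): calling twice returns identical
    tables.  Pass an explicit ``rng`` to draw independent realisations.
    """
    if substrate not in cfg.true_rates:
        raise ValueError(f"no true rates configured for substrate {substrate!r}")
    if rng is None:
        rng = cfg.rng("incubation")
    pool = _pool_for(cfg, substrate)
    nitrite_rate, n2o_rate = cfg.true_rates[substrate]
    points = _simulate_points(cfg, pool, nitrite_rate, n2o_rate, rng)
    return TimeCourse(
        station=station,
        depth=depth,
        substrate=substrate,
        treatment=treatment,
        pool=pool,
        points=points,
    )


def manipulation_truth(cfg: SimConfig, treatment: str) -> dict[str, tuple[float, float]]:
    """True (nitrite, N₂O) rates per substrate under a manipulation."""
    truth = {s: tuple(r) for s, r in cfg.true_rates.items()}
    if treatment == "plus_ammonium":
        nit, n2o = truth["urea"]
        truth["urea"] = (nit * cfg.inhibition_factor, n2o * cfg.inhibition_factor)
    elif treatment not in ("in_situ", "plus_urea"):
        raise ValueError(f"unknown treatment {treatment!r}")
    return truth


def simulate_manipulation(
    cfg: SimConfig,
    treatment: Literal["in_situ", "plus_ammonium", "plus_urea"],
    station: str = "CB2",
    depth: float = 11.5,
    rng: np.random.Generator | None = None,
) -> tuple[TimeCourse, TimeCourse]:
    """Paired ammonium- and urea-tracer incubations under a manipulation.

    ``plus_ammonium`` adds 2 µM unlabelled ammonium: the ammonium-pool
    label fraction is recomputed over the enlarged pool (the tracer spike
    was sized to the in-situ pool) and urea oxidation is multiplied by
    the inhibition factor.  ``plus_urea`` adds 18 µM N unlabelled urea
    and recomputes the urea-pool label fraction; ammonium oxidation is
    left unchanged.
    """
    truth = manipulation_truth(cfg, treatment)
    if rng is None:
        rng = cfg.rng("manipulation")
    courses = []
    for substrate in ("ammonium", "urea"):
        ambient = cfg.manipulation_pools[substrate]
        tracer = tracer_conc_for_F(ambient, cfg.F_targets[substrate])
        if treatment == "plus_ammonium" and substrate == "ammonium":
            ambient += cfg.nh4_addition
        if treatment == "plus_urea" and substrate == "urea":
            ambient += cfg.urea_addition
        pool = SubstratePool(species=substrate, ambient_conc=ambient, tracer_conc=tracer)
        nitrite_rate, n2o_rate = truth[substrate]
        points = _simulate_points(cfg, pool, nitrite_rate, n2o_rate, rng)
        courses.append(
            TimeCourse(
                station=station,
                depth=depth,
                substrate=substrate,
                treatment=treatment,
                pool=pool,
                points=points,
            )
        )
    return courses[0], courses[1]


def simulate_global_dataset(
    cfg: SimConfig,
    n_sites: int,
    rng: np.random.Generator | None = None,
) -> list[SiteRecord]:
    """Synthetic global compilation of paired concentrations and rates.

    Non-polar sites follow ``log10(rate ratio) = slope·log10(substrate
    ratio) + intercept + ε``; polar sites get an extra intercept shift
    (the anomalous high-rate-ratio, low-substrate-ratio regime).
    Absolute ammonium oxidation scales with ammonium concentration.
    Rates below the field detection limits (0.09 / 0.02 nmol N L⁻¹ d⁻¹)
    are flagged.
    """
    if n_sites < 10:
        raise ValueError("need n_sites >= 10")
    if rng is None:
        rng = cfg.rng("global")
    n_polar = int(round(cfg.outlier_fraction * n_sites))
    habitats = list(
        rng.choice(
            list(HABITAT_WEIGHTS),
            size=n_sites - n_polar,
            p=np.array(list(HABITAT_WEIGHTS.values())) / sum(HABITAT_WEIGHTS.values()),
        )
    ) + ["polar"] * n_polar
    records = []
    for i, habitat in enumerate(habitats):
        mu, sd = HABITAT_LOG10_SUBSTRATE_RATIO[habitat]
        log_x = rng.normal(mu, sd)
        nh4 = HABITAT_NH4_MEDIAN[habitat] * 10.0 ** rng.normal(0.0, 0.3)
        urea_N = nh4 * 10.0**log_x
        shift = cfg.polar_shift_log10 if habitat == "polar" else 0.0
        eps = rng.normal(0.0, cfg.scatter_log10) if cfg.scatter_log10 > 0 else 0.0
        log_y = cfg.global_slope * log_x + cfg.global_intercept + shift + eps
        nh4_ox = 20.0 * nh4 * 10.0 ** rng.normal(0.0, 0.3)
        urea_ox = nh4_ox * 10.0**log_y
        records.append(
            SiteRecord(
                region=habitat.replace("_", " ").title(),
                station=f"S{i:04d}",
                depth=float(rng.integers(5, 200)),
                nh4=nh4,
                urea_N=urea_N,
                nh4_ox=nh4_ox,
                urea_ox=urea_ox,
                habitat=habitat,
                nh4_ox_below_dl=bool(nh4_ox < 0.09),
                urea_ox_below_dl=bool(urea_ox < 0.02),
            )
        )
    return records


def simulate_coverage_table(
    cfg: SimConfig,
    n_samples: int,
    rng: np.random.Generator | None = None,
    noise: Literal["poisson", "none"] = "poisson",
) -> tuple[list[GeneCoverageRecord], pd.DataFrame]:
    """Synthetic per-gene coverage tables plus a truth sidecar.

    Each sample draws a substrate ratio (log-uniform over [0.3, 8], above
    the clamp point of the gene-ratio line), sets the true ureC:amoA
    ratio to ``max(0, slope·x + intercept)``, and Poisson-samples mean
    coverages around abundance × library size (libraries 10–100 M
    reads).  ``noise="none"`` emits exact expectations, under which the
    downstream linear fit recovers the generator line exactly.

    Returns (records, truth) where truth has one row per sample with the
    drawn substrate ratio and true gene ratio.
    """
    if n_samples < 3:
        raise ValueError("need n_samples >= 3")
    if rng is None:
        rng = cfg.rng("coverage")
    records: list[GeneCoverageRecord] = []
    truth_rows = []
    for i in range(n_samples):
        sid = f"MG{i:03d}"
        region = _COVERAGE_REGIONS[i % len(_COVERAGE_REGIONS)]
        x = 10.0 ** rng.uniform(math.log10(0.3), math.log10(8.0))
        true_ratio = max(0.0, cfg.generatio_slope * x + cfg.generatio_intercept)
        amoa_abund = 0.5 * 10.0 ** rng.normal(0.0, 0.3)  # coverage per M reads
        urec_abund = true_ratio * amoa_abund
        lib = float(rng.uniform(10.0, 100.0))
        n_hits = int(rng.integers(1, 4))
        split = rng.dirichlet(np.ones(n_hits)) if n_hits > 1 else np.array([1.0])
        for frac in split:
            lam = amoa_abund * frac * lib
            cov = float(rng.poisson(lam)) if noise == "poisson" else lam
            records.append(
                GeneCoverageRecord(
                    sample_id=sid,
                    region=region,
                    gene="amoA",
                    taxon_group="AOA",
                    mean_coverage=cov,
                    library_reads_millions=lib,
                )
            )
        if urec_abund > 0.0:
            lam = urec_abund * lib
            cov = float(rng.poisson(lam)) if noise == "poisson" else lam
            records.append(
                GeneCoverageRecord(
                    sample_id=sid,
                    region=region,
                    gene="ureC",
                    taxon_group="AOA",
                    mean_coverage=cov,
                    library_reads_millions=lib,
                )
            )
        truth_rows.append(
            {
                "sample_id": sid,
                "region": region,
                "substrate_ratio": x,
                "true_urec_amoa": true_ratio,
                "amoa_abundance": amoa_abund,
                "library_reads_millions": lib,
            }
        )
    return records, pd.DataFrame(truth_rows)
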