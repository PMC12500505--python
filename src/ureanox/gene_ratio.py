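"""ureC:amoA functional-gene coverage ratios.

The genetic capability of ammonia-oxidising archaea (AOA) to hydrolyse
urea is summarised per metagenomic sample as the ratio of urease
(*ureC*) to ammonia-monooxygenase (*amoA*) gene coverage, each first
normalised to sequencing depth (coverage per million reads; per-
nucleotide mean coverage needs no gene-length adjustment).  Region
medians and two linear fits — ratio vs. substrate ratio and oxidation-
rate ratio vs. gene ratio — connect the genomic metric to the
biogeochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crosssite_regression import InsufficientDataError, RegressionFit

__all__ = [
    "GeneCoverageRecord",
    "SampleGeneRatio",
    "normalize_coverage",
    "urec_amoa_ratio",
    "region_summary",
    "ratio_vs_substrate_fit",
    "ratio_vs_rate_ratio_fit",
    "MissingAmoAError",
]

GENES = ("amoA", "ureC")
TAXON_GROUPS = ("AOA", "AOB", "comammox", "other")


class MissingAmoAError(ValueError):
    """A sample without amoA coverage has an undefined ratio (not zero)."""


@dataclass(frozen=True)
class GeneCoverageRecord:
    """Per-sample, per-gene-hit mean coverage with library size."""

    sample_id: str
    region: str
    gene: str
    taxon_group: str
    mean_coverage: float
    library_reads_millions: float

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r}")
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon group {self.taxon_group!r}")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")
        if self.library_reads_millions <= 0:
            raise ValueError("library_reads_millions must be > 0")


@dataclass(frozen=True)
class SampleGeneRatio:
    """Depth-normalised amoA and ureC coverage and their ratio, one sample."""

    sample_id: str
    region: str
    amoa_norm: float
    urec_norm: float
    urec_amoa: float


def normalize_coverage(record: GeneCoverageRecord) -> float:
    """Coverage per million reads: mean coverage / library size (M reads)."""
    return record.mean_coverage / record.library_reads_millions


def urec_amoa_ratio(
    records: Sequence[GeneCoverageRecord], taxon: str = "AOA"
) -> SampleGeneRatio:
    """ureC:amoA ratio for one sample's coverage records.

    Multiple gene hits are summed (normalised coverage approximates gene
    copies) before forming the ratio.  A sample with ureC absent gets a
    genuine ratio of 0; a sample with amoA absent raises
    :class:`MissingAmoAError` — the ratio is missing, never ∞ or 0.
    """
    recs = [r for r in records if r.taxon_group == taxon]
    if not recs:
        raise MissingAmoAError(f"no {taxon} coverage records in sample")
    sample_ids = {r.sample_id for r in recs}
    if len(sample_ids) != 1:
        raise ValueError(f"records span multiple samples: {sorted(sample_ids)}")
    amoa = sum(normalize_coverage(r) for r in recs if r.gene == "amoA")
    urec = sum(normalize_coverage(r) for r in recs if r.gene == "ureC")
    if amoa <= 0.0:
        raise MissingAmoAError(
            f"sample {recs[0].sample_id}: no positive {taxon} amoA coverage; "
            "ureC:amoA undefined"
        )
    return SampleGeneRatio(
        sample_id=recs[0].sample_id,
        region=recs[0].region,
        amoa_norm=amoa,
        urec_norm=urec,
        urec_amoa=urec / amoa,
    )


def sample_ratios(
    records: Iterable[GeneCoverageRecord], taxon: str = "AOA"
) -> list[SampleGeneRatio]:
    """Per-sample ratios for a whole coverage table; amoA-free samples dropped."""
    by_sample: dict[str, list[GeneCoverageRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    out = []
    for sid in sorted(by_sample):
        try:
            out.append(urec_amoa_ratio(by_sample[sid], taxon=taxon))
        except MissingAmoAError:
            continue
    return out


def region_summary(ratios: Sequence[SampleGeneRatio]) -> pd.DataFrame:
    """Median, quartiles and n of the ureC:amoA ratio per region."""
    if not ratios:
        raise InsufficientDataError("no sample ratios to summarise")
    df = pd.DataFrame(
        {"region": [r.region for r in ratios], "urec_amoa": [r.urec_amoa for r in ratios]}
    )
    g = df.groupby("region")["urec_amoa"]
    out = g.agg(
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        n="count",
    ).reset_index()
    return out


def _linear_fit(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 pairs, have {n}")
    if np.ptp(x) == 0.0:
        raise InsufficientDataError("degenerate fit: predictor is constant")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
        residual_sd=float(np.sqrt(np.sum(resid**2) / max(n - 2, 1))),
        method="ols",
        outlier_flags=tuple(False for _ in range(n)),
    )


def ratio_vs_substrate_fit(
    paired: Sequence[tuple[float, float]]
) -> RegressionFit:
    """OLS of ureC:amoA ratio on urea:ammonium concentration ratio.

    Linear (not log) scale: pairs are (substrate ratio, gene ratio).
    """
    arr = np.asarray(paired, dtype=float)
    return _linear_fit(arr[:, 0], arr[:, 1])


def ratio_vs_rate_ratio_fit(
    paired: Sequence[tuple[float, float]]
) -> RegressionFit:
    """OLS of urea:ammonium oxidation-rate ratio on ureC:amoA gene ratio.

    Linear scale: pairs are (gene ratio, rate ratio).
    """
    arr = np.asarray(paired, dtype=float)
    return _linear_fit(arr[:, 0], arr[:, 1])
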