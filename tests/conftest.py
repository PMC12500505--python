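import numpy as np
import pytest

from ureanox import SimConfig, SiteRecord


@pytest.fixture
def cfg():
    return SimConfig(seed=42)


def make_site(x_ratio, y_ratio, habitat="open_ocean", station="S0", nh4=1.0, nh4_ox=10.0):
    """A ratio-eligible SiteRecord with the given substrate and rate ratios."""
    return SiteRecord(
        region=habitat,
        station=station,
        depth=10.0,
        nh4=nh4,
        urea_N=nh4 * x_ratio,
        nh4_ox=nh4_ox,
        urea_ox=nh4_ox * y_ratio,
        habitat=habitat,
    )


def powerlaw_sites(x_values, slope, intercept, habitat="open_ocean", rng=None, scatter=0.0):
    """Sites exactly (or noisily) on y = 10^(slope·log10 x + intercept)."""
    sites = []
    for i, x in enumerate(x_values):
        eps = rng.normal(0.0, scatter) if (rng is not None and scatter > 0) else 0.0
        y = 10.0 ** (slope * np.log10(x) + intercept + eps)
        sites.append(make_site(x, y, habitat=habitat, station=f"S{i}"))
    return sites
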