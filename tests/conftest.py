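import numpy as np
import pytest

from dosetrait import (
    SplineModelSpec,
    TraitConfig,
    extract_traits,
    fit_gamma_gam,
    load_paper_fixture,
)
from dosetrait.pipeline import STUDY_FITS

#: published trait values (p_max, t_max, mu, sigma) and fitted maxima f(p_max)
PUBLISHED_TRAITS = {
    ("glucose", "biomass"): dict(p_max=0.61, t_max=0.97, mu=0.50, sigma=0.26),
    ("sodium_acetate", "biomass"): dict(p_max=0.25, t_max=0.55, mu=0.27, sigma=0.15),
    ("glycerol", "biomass"): dict(p_max=0.39, t_max=0.73, mu=0.37, sigma=0.20),
    ("sodium_acetate", "ara_concentration"): dict(p_max=0.25, mu=0.27, sigma=0.15),
    ("glycerol", "ara_concentration"): dict(p_max=0.40, t_max=0.76, mu=0.38, sigma=0.19),
}

PUBLISHED_F_PMAX = {
    ("glucose", "biomass"): 15.77,
    ("glycerol", "biomass"): 15.88,
    ("sodium_acetate", "ara_concentration"): 178.0,
    ("glycerol", "ara_concentration"): 222.3,
}


@pytest.fixture(scope="session")
def fixture_fits():
    """Default-configuration fits + traits of all five study tables."""
    out = {}
    for source, kind in STUDY_FITS:
        table = load_paper_fixture(source, kind)
        curve = fit_gamma_gam(table, SplineModelSpec())
        out[(source, kind)] = (curve, extract_traits(curve, TraitConfig()))
    return out


@pytest.fixture()
def glucose_fit(fixture_fits):
    return fixture_fits[("glucose", "biomass")][0]


def chunked_mean(curve, xs, chunk=200_000):
    """Evaluate curve.mean over a huge grid without large temporaries."""
    parts = [curve.mean(xs[i:i + chunk]) for i in range(0, len(xs), chunk)]
    return np.concatenate(parts)
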