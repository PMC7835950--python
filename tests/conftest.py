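import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from oxokinetics.fitting import SaturationSeries
from oxokinetics.models import SiteParams, TwoSiteParams, mm_rate, two_site_rate
from oxokinetics.simulate import DEFAULT_SUBSTRATE_GRID

HEART_OG = SiteParams(km=0.45, amax=0.73)
LIVER_OA = TwoSiteParams(
    site1=SiteParams(km=0.0077, amax=0.0018),
    site2=SiteParams(km=0.45, amax=0.0075),
)
GRID = np.array([s for s in DEFAULT_SUBSTRATE_GRID if s > 0])


@pytest.fixture
def heart_og_params():
    return HEART_OG


@pytest.fixture
def liver_oa_params():
    return LIVER_OA


@pytest.fixture
def exact_one_site_series():
    """Noise-free Michaelis-Menten series on the standard 12-point grid."""

    def build(km=0.45, amax=0.73, grid=GRID, **kwargs):
        p = SiteParams(km=km, amax=amax)
        return SaturationSeries.from_arrays(grid, mm_rate(grid, p), **kwargs)

    return build


@pytest.fixture
def exact_two_site_series():
    """Noise-free biphasic series from the hepatic two-site ground truth."""

    def build(params=LIVER_OA, grid=GRID, **kwargs):
        return SaturationSeries.from_arrays(
            grid, two_site_rate(grid, params), **kwargs
        )

    return build
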