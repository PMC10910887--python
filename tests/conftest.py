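import numpy as np
import pytest

import idmincidence as idm


@pytest.fixture(scope="session")
def benchmark():
    """Default two-sex benchmark dataset (biennial 2011-2021, ages 50-99)."""
    return idm.make_benchmark_dataset(seed=1)


@pytest.fixture
def flat_prevalence():
    """3 years x 3 ages constant prevalence 0.05."""
    return idm.PrevalenceSurface(
        sex="male",
        years=[2011.0, 2013.0, 2015.0],
        ages=[60.0, 61.0, 62.0],
        values=np.full((3, 3), 0.05),
    )


def make_affine_prevalence(age_slope, year_slope, years=None, ages=None, sex="male"):
    """p(t, a) = age_slope*(a-50) + year_slope*(t-2011); exact for bilinear
    interpolation and central differences."""
    years = np.asarray(years if years is not None else np.arange(2011.0, 2022.0, 2.0))
    ages = np.asarray(ages if ages is not None else np.arange(50.0, 100.0, 1.0))
    T, A = np.meshgrid(years, ages, indexing="ij")
    return idm.PrevalenceSurface(
        sex=sex, years=years, ages=ages,
        values=age_slope * (A - 50.0) + year_slope * (T - 2011.0),
    )
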