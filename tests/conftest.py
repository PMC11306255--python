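import warnings

import pytest

from pubsitar import SimConfig, derive_all_measures, fit_sitar, simulate_cohort
from pubsitar.sitar import SitarSpec


@pytest.fixture(scope="session")
def height_cohort():
    """Height-only cohort with complete clinic attendance, n=300/sex."""
    cfg = SimConfig(n_per_sex=300, missingness_clinic=0.0).with_measures(
        ["height"])
    return cfg, simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def height_fit_f(height_cohort):
    cfg, cohort = height_cohort
    data = cohort.measurements[cohort.measurements["sex"] == "F"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_sitar(data, SitarSpec(outcome="height", n_knots=4))
    return cfg, cohort, fit


@pytest.fixture(scope="session")
def full_cohort():
    """All nine measures at modest size for derivation tests."""
    cfg = SimConfig(n_per_sex=80)
    return cfg, simulate_cohort(cfg, seed=21)


@pytest.fixture(scope="session")
def derived_full(full_cohort):
    cfg, cohort = full_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = derive_all_measures(cohort.measurements)
    return cfg, cohort, result
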