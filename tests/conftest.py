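import numpy as np
import pytest

import centiledesign as cd


@pytest.fixture(scope="session")
def truth():
    return cd.default_truth()


@pytest.fixture(scope="session")
def constant_model():
    """Flat chart: mu = 100, sigma = 10 over 14-42 weeks."""
    return cd.GrowthCurveModel(
        mean_coefficients=(100.0,),
        sd_coefficients=(10.0,),
        ga_domain=(14.0, 42.0),
        unit="mm",
    )


@pytest.fixture(scope="session")
def small_study():
    """Two-site triplicate study, 60 subjects per site, seed 7."""
    scenario = cd.default_scenario(seed=7, n_sites=2, n_subjects_per_site=60)
    data, bundle = cd.generate_study(scenario)
    return scenario, data, bundle


def simulate_cross_sectional(truth, n, rng, lo=14.0, hi=42.0):
    """One independent draw per subject at a uniform GA — shared helper."""
    w = rng.uniform(lo, hi, n)
    y = truth.mean_array(w) + truth.sd_array(w) * rng.standard_normal(n)
    return w, y
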