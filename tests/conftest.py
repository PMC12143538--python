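import numpy as np
import pytest

from matchstab.cohorts import (
    CovariateSpec,
    ScenarioConfig,
    calibrate_outcome,
    calibrate_propensity,
    generate_cohort,
)


@pytest.fixture(scope="session")
def unimodal():
    return CovariateSpec("unimodal")


@pytest.fixture(scope="session")
def calibrated_02_085(unimodal):
    """Propensity model for treated fraction 0.2, c-statistic 0.85."""
    return calibrate_propensity(unimodal, 0.2, 0.85)


@pytest.fixture(scope="session")
def calibrated_outcome_or05(unimodal, calibrated_02_085):
    return calibrate_outcome(unimodal, calibrated_02_085, 0.5, 0.3)


@pytest.fixture(scope="session")
def small_cohort():
    """A moderate cohort with events in both arms, for estimator tests."""
    cfg = ScenarioConfig(covariate=CovariateSpec("unimodal"), pg=0.3, c_target=0.7,
                         pe=0.4, true_or=1.0, n=200)
    return generate_cohort(cfg, 11)


def rand_instance(rng, n_max=40, tied=False):
    """A random small matching instance (logit scores + treatment)."""
    n = int(rng.integers(4, n_max))
    if tied:
        lp = rng.choice(np.linspace(-1.0, 1.0, 5), size=n)
    else:
        lp = rng.normal(size=n)
    t = rng.integers(0, 2, size=n)
    if t.sum() == 0:
        t[0] = 1
    if t.sum() == n:
        t[-1] = 0
    return lp, t
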