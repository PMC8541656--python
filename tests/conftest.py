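import numpy as np
import pytest
from hypothesis import settings

import grainmod as gm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return gm.SyntheticConfig(seed=2017)


@pytest.fixture(scope="session")
def bundle(config):
    """Default synthetic inputs with both survival models fitted."""
    return gm.default_bundle(config=config)


@pytest.fixture(scope="session")
def model(bundle):
    return bundle.model()


@pytest.fixture(scope="session")
def mstar(model):
    """Calibrated incidence hazard multiplier."""
    return gm.calibrate_incidence(model)


@pytest.fixture(scope="session")
def life_table(config):
    return gm.generate_life_table(config)


@pytest.fixture(scope="session")
def exponential_fit():
    """Hand-built shape-1 fit with scale 10 and no covariates."""
    return gm.WeibullFit(
        shape=1.0,
        coefficients={"intercept": float(np.log(10.0))},
        covariance=np.zeros((2, 2)),
        param_names=["log_shape", "intercept"],
        loglik=0.0, aic=0.0, bic=0.0, n=100, n_events=100,
        covariates=[],
    )
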