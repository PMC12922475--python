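import numpy as np
import pytest

from harpseal_ipm.inference import IPMModel, fit_model
from harpseal_ipm.synthetic import fixture_small


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def fixture_bundle():
    """The deterministic 15-year / 12-age miniature study."""
    scenario, env, effects, state, obs = fixture_small()
    return {"scenario": scenario, "env": env, "effects": effects,
            "state": state, "obs": obs}


@pytest.fixture(scope="session")
def tiny_fit(fixture_bundle):
    """A short posterior fit on the miniature study, shared across
    diagnostic tests (speed over precision)."""
    b = fixture_bundle
    model = IPMModel(b["obs"], b["env"],
                     base_params=b["scenario"].params.copy(),
                     n_ages=b["scenario"].n_ages)
    return fit_model(model, n_chains=2, n_burn=80, n_steps=40, seed=3)
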