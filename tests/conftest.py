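import numpy as np
import pytest

from saccrace import ModelParams, SessionPlan, make_population, synthesize_session


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_session(params):
    """A compact synthetic session shared by pipeline-level tests."""
    rng = np.random.default_rng(20240917)
    pop = make_population(10, rng)
    plan = SessionPlan(n_trials=400)
    return synthesize_session(pop, plan, params, rng)
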