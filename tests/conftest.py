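import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_params():
    from cims import CIMSParams

    return CIMSParams()


@pytest.fixture(scope="session")
def exp1_table():
    """A moderate synthetic repetition-with-co-articulation dataset."""
    from cims import GeneratorParams, build_design, simulate_trials

    design = build_design(1, {"n_participants": 24})
    gen = GeneratorParams(
        intercept=-0.1,
        condition_effects={"six_rep": 1.1, "control": 1.0},
        tau_participant=1.0,
        tau_stimulus=0.3,
        seed=555,
    )
    return simulate_trials(design, gen)
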