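import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ogttlab.cohort import CohortSpec, generate_cohort
from ogttlab.edes import ModelParameters, OGTT_TIMES, SubjectContext, simulate
from ogttlab.fitting import OGTTResponse

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params0() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def ctx() -> SubjectContext:
    return SubjectContext()


@pytest.fixture(scope="session")
def ngm_curve(params0, ctx) -> OGTTResponse:
    """Noiseless simulated response of the default normoglycemic archetype."""
    sim = simulate(params0, ctx, 5.0, 8.0, list(OGTT_TIMES))
    assert sim.success
    return OGTTResponse("NGM_ARCH", np.array(OGTT_TIMES), sim.g_traj, sim.i_traj)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-subject mixed cohort with default noise and missingness."""
    return generate_cohort(CohortSpec(n=30, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """A 25-subject cohort without missing samples (for scenario runs)."""
    return generate_cohort(CohortSpec(n=25, seed=7, missing_prob=0.0))
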