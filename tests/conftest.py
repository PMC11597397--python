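import pytest
from hypothesis import HealthCheck, settings

import bombpulse as bp

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def narwhal():
    """The bundled 46-sample narwhal growth-layer dataset."""
    return bp.bundled_narwhal_dataset()


@pytest.fixture(scope="session")
def narwhal_fit(narwhal):
    """Four-parameter weighted NLS fit to the narwhal data."""
    return bp.fit_pulse(narwhal, variant=bp.FOUR_PARAM)


@pytest.fixture(scope="session")
def narwhal_boot(narwhal_fit):
    """Narwhal fit with 1000-replicate residual-bootstrap 95% bands."""
    return bp.bootstrap_ci(narwhal_fit, n_boot=1000, seed=1)


@pytest.fixture(scope="session")
def synthetic_five_fit():
    """Converged five-parameter fit to one synthetic all-species-like cohort."""
    ds = bp.simulate_cohort(bp.CohortSpec(seed=7))
    fit = bp.fit_pulse(ds, variant=bp.FIVE_PARAM, seed=3)
    assert fit.converged
    return fit
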