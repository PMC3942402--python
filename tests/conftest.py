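import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

TRUE_ALPHA = 1.234
TRUE_LAM = 0.01595


@pytest.fixture(scope="session")
def ee_cohort():
    """One simulated cohort of 298 EE survival times (months), fixed seed."""
    from eesurv import sample

    return sample("ee", (TRUE_ALPHA, TRUE_LAM), 298, seed=11)


@pytest.fixture(scope="session")
def ee_mcmc_draws(ee_cohort):
    """A shared scaled-down EE chain on the session cohort."""
    from eesurv import McmcConfig, PriorBox, run_mcmc

    return run_mcmc(
        "ee",
        ee_cohort,
        box=PriorBox.wide(2),
        config=McmcConfig(iterations=5_000, burn_in=1_000, seed=7),
    )


@pytest.fixture(scope="session")
def posterior_grid(ee_cohort):
    from eesurv import build_posterior_grid

    return build_posterior_grid(ee_cohort)
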