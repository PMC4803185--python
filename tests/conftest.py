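import math

import numpy as np
import pytest

from slclock import SLParams

#: the study conditions of the emulated low-density culture
PAPER_OMEGA = 2 * math.pi / 78.0
PAPER_SIGMA_Z2 = 0.486
PAPER_SIGMA_MU2 = 6.84
PAPER_TAU_MU = 476.0


@pytest.fixture(scope="session")
def paper_params() -> SLParams:
    """Deterministic baseline: mu=1, b=1, 78-min period, no noise."""
    return SLParams()


@pytest.fixture(scope="session")
def additive_noise_params() -> SLParams:
    """Additive noise only, at the level matched to the persistent cells."""
    return SLParams(sigma_z2=PAPER_SIGMA_Z2)


@pytest.fixture(scope="session")
def full_noise_params() -> SLParams:
    """Colored + additive noise as in the emulated cohort."""
    return SLParams(sigma_z2=PAPER_SIGMA_Z2, sigma_mu2=PAPER_SIGMA_MU2,
                    tau_mu=PAPER_TAU_MU)


def ensemble_traces(params: SLParams, n: int, seed: int, dt_sample: float = 2.0):
    from slclock import render_trace, simulate_ensemble

    return [render_trace(t, dt_sample)
            for t in simulate_ensemble(params, n, seed=seed)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
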