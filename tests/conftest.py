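import numpy as np
import pytest

from photocyt import IlluminationProtocol, RateSet


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def oracle_protocol():
    """Single flash at t=0, fine sampling over 2 ms."""
    return IlluminationProtocol(mode="flash_train", duration=2e-3,
                                flash_times=(0.0,), sampling_dt=1e-5)


def two_branch_rates(k_a: float, k_d: float) -> RateSet:
    """One irreversible donor branch and one irreversible acceptor branch.

    All other chemistry is switched off so the ODE reduces to the two-branch
    re-opening scheme behind the closed-form law.
    """
    return RateSet(k_L=0.0, k_AB1=k_a, k_AB2=0.0, k_Qex=0.0,
                   k_bind=0.0, k_unbind=0.0, k_ET=k_d,
                   N_pool=10.0, k_bc1=0.0)
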