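import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from korab import KineticParameters, make_variant  # noqa: E402


@pytest.fixture(scope="session")
def uu_params() -> KineticParameters:
    """The partial-repression-by-both variant at its fitted rates."""
    return make_variant("uu")


@pytest.fixture(scope="session")
def generic_params() -> KineticParameters:
    """A parameter set with every process active (sigma > 0)."""
    return KineticParameters(k_A=11.5, k_B=3.2, sigma_A=1e-4, sigma_B=2e-4,
                             pi_X=0.72, pi_Y=0.72)


def promoter_occupancy_nullspace(a, b, k1, k2, k3, k4):
    """Independent oracle: stationary distribution of the explicit 4x4
    rate matrix of the binding chain D<->X<->Z<->Y<->D (states D, X, Y, Z),
    found as the null space of the generator."""
    Q = np.zeros((4, 4))
    Q[0, 1] = a   # D -> X  (KorA binds)
    Q[1, 0] = k1  # X -> D
    Q[0, 2] = b   # D -> Y  (KorB binds)
    Q[2, 0] = k2  # Y -> D
    Q[1, 3] = b   # X -> Z  (KorB joins KorA-DNA)
    Q[3, 1] = k4  # Z -> X
    Q[2, 3] = a   # Y -> Z  (KorA joins KorB-DNA)
    Q[3, 2] = k3  # Z -> Y
    A = Q.T - np.diag(Q.sum(axis=1))
    M = np.vstack([A, np.ones(4)])
    rhs = np.zeros(5)
    rhs[4] = 1.0
    sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    return sol  # order: D, X, Y, Z
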