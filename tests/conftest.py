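import numpy as np
import pytest

from bundlemech import BundleState, ModelParams


@pytest.fixture
def small_params():
    """A small bundle cheap enough for exhaustive finite differencing."""
    return ModelParams(m=4, n=8, L=2.0, K=2.0, B_in=1.0, B_r=2.0,
                       Nc=0.7, Np=0.1, boundary="clamped")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_state(params: ModelParams, rng, scale: float = 0.05) -> BundleState:
    return BundleState(rng.normal(0.0, scale, (params.m, params.n)))


def fd_gradient(params: ModelParams, state: BundleState,
                h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of the total energy (test oracle)."""
    from bundlemech import total_energy

    theta = state.theta
    g = np.zeros_like(theta)
    for i in range(theta.shape[0]):
        for j in range(theta.shape[1]):
            tp = theta.copy()
            tp[i, j] += h
            tm = theta.copy()
            tm[i, j] -= h
            g[i, j] = (
                total_energy(params, BundleState(tp)).total
                - total_energy(params, BundleState(tm)).total
            ) / (2.0 * h)
    return g
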