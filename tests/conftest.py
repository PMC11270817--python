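import numpy as np
import pytest

from flowfe import (
    BaseUniform,
    GaussianMixtureSystem,
    SplineCouplingFlow,
    build_toy_system,
)


@pytest.fixture(scope="session")
def toy_system():
    return build_toy_system()


@pytest.fixture(scope="session")
def gaussian_trio():
    """Three well-separated single-Gaussian 1D states with closed-form f and s."""
    return GaussianMixtureSystem(
        means=[[[0.0]], [[2.0]], [[5.0]]],
        sigmas=[[0.3], [0.15], [0.5]],
        masses=[[1.0], [0.5], [2.0]],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def perturbed_flow(dim: int, noise: float = 0.1, seed: int = 7,
                   n_layers: int = 4, n_bins: int = 16) -> SplineCouplingFlow:
    """A flow pushed a realistic distance away from its identity start."""
    flow = SplineCouplingFlow(dim, n_layers=n_layers, n_bins=n_bins, seed=seed)
    prng = np.random.default_rng(seed + 1)
    for layer in flow.layers:
        for key in layer.params:
            layer.params[key] = layer.params[key] + noise * prng.standard_normal(
                layer.params[key].shape
            )
    return flow


@pytest.fixture
def unit_base():
    def make(dim):
        return BaseUniform(dim)

    return make
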