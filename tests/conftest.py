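import numpy as np
import pytest

from deerflex import (
    BackgroundModel,
    DistanceDistribution,
    InversionConfig,
    build_kernel,
    compose_trace,
    default_grid,
    form_factor,
)


@pytest.fixture(scope="session")
def grid():
    """Default fine distance grid (1.5-8.0 nm, 0.02 nm)."""
    return default_grid()


@pytest.fixture(scope="session")
def coarse_config():
    """Inversion configuration used for round-trip tests (0.05 nm grid)."""
    return InversionConfig(dr=0.05)


@pytest.fixture
def gaussian_dist(grid):
    def make(mean=3.5, sd=0.3):
        return DistanceDistribution.from_gaussian_mixture(grid, [(1.0, mean, sd)])

    return make


@pytest.fixture
def simulated_trace(grid):
    """Factory for traces composed from a Gaussian mixture with known truth."""

    def make(
        components=((1.0, 3.5, 0.3),),
        lam=0.3,
        k=0.05,
        noise_sigma=0.0,
        seed=0,
        t_max=4.0,
        n_points=256,
    ):
        truth = DistanceDistribution.from_gaussian_mixture(grid, list(components))
        t = np.linspace(0.0, t_max, n_points)
        F = form_factor(build_kernel(t, grid), truth)
        bg = BackgroundModel(k=k, lam=lam)
        trace = compose_trace(t, F, bg, noise_sigma, seed=seed)
        return trace, truth, bg

    return make


@pytest.fixture(scope="session")
def toy_structure():
    from deerflex import make_toy_structure

    return make_toy_structure(n_residues_per_helix=20, n_helices=2, seed=11)
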