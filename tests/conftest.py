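import numpy as np
import pytest

from nwaymeta import (
    ConvergenceControls,
    HCConfig,
    TrajectoryTensor,
    fit_hcplsr_classical,
    fit_hcplsr_inverse,
    goodwin_demo_system,
    make_synthetic_trilinear,
    simulate_to_limit_cycle,
)


@pytest.fixture(scope="session")
def small_tensor() -> TrajectoryTensor:
    rng = np.random.default_rng(7)
    return TrajectoryTensor(
        rng.normal(size=(5, 3, 7)),
        [f"o{i}" for i in range(5)],
        ["A", "B", "C"],
        np.arange(7) / 7,
        period=24.0 + rng.uniform(size=5),
    )


@pytest.fixture(scope="session")
def single_regime():
    """Noise-free rank-3 trilinear data, one regime."""
    return make_synthetic_trilinear(
        n_obs=200, n_vars=6, n_time=20, n_factors=3, n_regimes=1, noise_sd=0.0, seed=1
    )


@pytest.fixture(scope="session")
def three_regimes():
    """Moderate-size regime-structured fixture for hierarchical tests."""
    return make_synthetic_trilinear(n_obs=600, seed=2)


@pytest.fixture(scope="session")
def fitted_hierarchy(three_regimes):
    """Inverse + classical hierarchical models on the 3-regime fixture."""
    table, tensor, truth = three_regimes
    config = HCConfig(n_clusters=3, a_max=8, seed=0)
    inverse = fit_hcplsr_inverse(tensor, table, config)
    classical = fit_hcplsr_classical(table, tensor, inverse)
    return inverse, classical


@pytest.fixture(scope="session")
def goodwin_cycle():
    result = simulate_to_limit_cycle(goodwin_demo_system(), {}, ConvergenceControls())
    return result
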