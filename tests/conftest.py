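import numpy as np
import pytest

from tosccamm import (
    LongitudinalView,
    PairedLongitudinalData,
    SimulationConfig,
    TrajectorySpec,
    generate,
)


@pytest.fixture(scope="session")
def cubic_spec() -> TrajectorySpec:
    return TrajectorySpec("random_intercept_polynomial", degree=3)


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down simulated dataset (same generative process, fewer features)."""
    return generate(SimulationConfig(n=60, p=300, q=60, seed=7))


@pytest.fixture(scope="session")
def default_sim():
    """Full-size simulated dataset at the generator's default conditions."""
    return generate(SimulationConfig(seed=1))


def make_single_visit_pair(rng: np.random.Generator, n: int, p: int, q: int, signal: float = 0.0):
    """Paired views with one visit per individual at a common time, optionally
    sharing a latent factor; columns standardized."""
    ids = np.array([f"i{j:03d}" for j in range(n)], dtype=object)
    z = rng.standard_normal(n)
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    if signal:
        X[:, 0] += signal * z
        Y[:, 0] += signal * z
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    times = np.zeros(n)
    return PairedLongitudinalData(
        LongitudinalView(ids, times, X), LongitudinalView(ids, times, Y)
    )
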