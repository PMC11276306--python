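import numpy as np
import pytest

from igpid import (
    BENCHMARK,
    BlockSpec,
    CrossCorrelationSystem,
    PartitionedCovariance,
    equicorr_system,
    standardize,
)


def random_covariance(rng: np.random.Generator, blocks: BlockSpec) -> PartitionedCovariance:
    """A well-conditioned random PD covariance with the given block structure."""
    m = blocks.m
    a = rng.normal(size=(m, 2 * m))
    sigma = a @ a.T / (2 * m) + 0.5 * np.eye(m)
    return PartitionedCovariance(sigma=sigma, blocks=blocks)


def random_system(
    rng: np.random.Generator, max_dim: int = 4, blocks: BlockSpec | None = None
) -> CrossCorrelationSystem:
    """A random valid standardised system with dims drawn up to ``max_dim``."""
    if blocks is None:
        n1, n2, n3 = rng.integers(1, max_dim + 1, size=3)
        blocks = BlockSpec(int(n1), int(n2), int(n3))
    return standardize(random_covariance(rng, blocks))


def scalar_system(p: float, q: float, r: float) -> CrossCorrelationSystem:
    return CrossCorrelationSystem(
        p=np.array([[p]]), q=np.array([[q]]), r=np.array([[r]]),
        blocks=BlockSpec(1, 1, 1),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240625)


@pytest.fixture(scope="session")
def benchmark_system() -> CrossCorrelationSystem:
    """The (p, q, r) = (-0.15, 0.15, 0.15), blocks (3, 4, 3) benchmark."""
    return equicorr_system(BENCHMARK)
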