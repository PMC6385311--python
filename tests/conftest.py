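import numpy as np
import pytest

from brwhnha import AssociationMatrix, SynthConfig, generate_network


def random_association(
    rng: np.random.Generator, n_m: int, n_d: int, density: float, ensure_edge: bool = True
) -> AssociationMatrix:
    a = (rng.random((n_m, n_d)) < density).astype(np.int8)
    if ensure_edge and a.sum() == 0:
        a[rng.integers(n_m), rng.integers(n_d)] = 1
    return AssociationMatrix(
        a,
        [f"m{i:03d}" for i in range(n_m)],
        [f"d{j:03d}" for j in range(n_d)],
    )


@pytest.fixture
def small_assoc() -> AssociationMatrix:
    """The 2x2 worked example A = [[1,0],[1,1]]: degrees k_m=(1,2), k_d=(2,1)."""
    return AssociationMatrix([[1, 0], [1, 1]], ["m1", "m2"], ["d1", "d2"])


@pytest.fixture(scope="session")
def canonical_network():
    """The canonical planted-block fixture: 200x40, 5 blocks, seed 7."""
    return generate_network(SynthConfig())


@pytest.fixture(scope="session")
def null_network():
    """Density-matched null: within = background = the planted config's
    expected overall density (0.038), so no block signal remains."""
    cfg = SynthConfig(
        within_block_assoc_prob=0.038, background_assoc_prob=0.038, seed=7
    )
    return generate_network(cfg)
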