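import numpy as np
import pytest

from mdlink.data_io import AssociationMatrix


def random_binary_matrix(nd: int, nm: int, seed: int, p: float = 0.3) -> AssociationMatrix:
    """Random binary adjacency with no all-zero rows or columns."""
    rng = np.random.default_rng(seed)
    while True:
        values = (rng.random((nd, nm)) < p).astype(float)
        if values.sum(axis=0).all() and values.sum(axis=1).all():
            return AssociationMatrix(
                values,
                [f"d{i}" for i in range(nd)],
                [f"m{j}" for j in range(nm)],
            )


@pytest.fixture
def small_assoc() -> AssociationMatrix:
    return random_binary_matrix(6, 8, seed=42)


@pytest.fixture
def tiny_assoc() -> AssociationMatrix:
    """2x2 identity adjacency used by the worked similarity examples."""
    return AssociationMatrix(np.eye(2), ["d0", "d1"], ["m0", "m1"])
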