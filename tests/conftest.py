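import numpy as np
import pytest

from mecotest import AlterationMatrix


@pytest.fixture
def tiny_matrix() -> AlterationMatrix:
    """5 genes x 5 tumors; genes 'G3' and 'G5' are each altered in 2 of 5
    tumors with overlap 2 (the two high-load tumors)."""
    values = np.array(
        [
            [1, 1, 0, 0, 0],
            [0, 1, 1, 0, 0],
            [1, 1, 0, 0, 0],
            [0, 0, 0, 1, 1],
            [1, 1, 0, 0, 0],
        ]
    )
    return AlterationMatrix(
        values, ["G1", "G2", "G3", "G4", "G5"], [f"T{i}" for i in range(1, 6)]
    )


@pytest.fixture
def random_matrix() -> AlterationMatrix:
    """Seeded random 10 x 15 binary matrix without degenerate margins."""
    rng = np.random.default_rng(42)
    while True:
        v = (rng.uniform(size=(10, 15)) < 0.35).astype(int)
        if v.sum(axis=1).min() > 0 and v.sum(axis=0).min() > 0:
            break
    return AlterationMatrix(
        v, [f"g{i}" for i in range(10)], [f"t{j}" for j in range(15)]
    )
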