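import numpy as np
import pytest

from concord import PValueMatrix


@pytest.fixture
def toy_matrix():
    """Five features, two lists, hand-listed p-values."""
    values = np.array(
        [
            [0.005, 0.20],
            [0.01, 0.01],
            [0.50, 0.02],
            [0.02, 0.90],
            [0.95, 0.95],
        ]
    )
    return PValueMatrix(
        feature_ids=np.array([f"g{i}" for i in range(5)], dtype=object),
        values=values,
        experiment_names=["liver", "muscle"],
    )


def random_matrix(rng, n, L):
    """A uniform random matrix with unique ids."""
    return PValueMatrix(
        feature_ids=np.array([f"f{i:04d}" for i in range(n)], dtype=object),
        values=rng.random((n, L)),
        experiment_names=[f"exp{l}" for l in range(L)],
    )
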