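import numpy as np
import pandas as pd
import pytest

from batchray import FeatureMatrix, SampleAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_matrix():
    """3 features x 4 samples, hand-typed values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [0.5, -0.5, 1.5, -1.5],
            [10.0, 10.0, 12.0, 12.0],
        ]
    )
    return FeatureMatrix(values, ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def small_annotation():
    table = pd.DataFrame(
        {
            "batch": ["b1", "b1", "b2", "b2"],
            "sex": ["f", "m", "f", "m"],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return SampleAnnotation(table)


def random_grouped_instance(rng, n_max=50, d_max=200, k_max=6):
    """A random (data, labels) instance with >=2 groups of >=2 members."""
    k = int(rng.integers(2, k_max + 1))
    d = int(rng.integers(1, d_max + 1))
    sizes = rng.integers(2, max(3, n_max // k) + 1, size=k)
    data = rng.standard_normal((int(sizes.sum()), d))
    # give groups distinct mean offsets so db > 0 generically
    offsets = rng.normal(scale=2.0, size=(k, d))
    labels = np.repeat(np.arange(k), sizes)
    data += offsets[labels]
    return data, [f"g{j}" for j in labels]
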