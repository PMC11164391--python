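import numpy as np
import pytest

from scpmp import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blobs3():
    """Three well-separated Gaussian blobs in 2-D with planted labels."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    pts = [c + rng.normal(scale=0.5, size=(40, 2)) for c in centers]
    labels = np.repeat([1, 2, 3], 40)
    return DataMatrix(values=np.vstack(pts)), labels


@pytest.fixture
def planar_points(rng):
    """A centered planar point set whose Euclidean distances are exactly MDS-embeddable."""
    P = rng.normal(size=(12, 2))
    return P - P.mean(axis=0)
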