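import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path3_graph():
    """Three collinear locations at 0, 1, 3: MST is the path 0-1-2."""
    from spacebf.graph import build_mst

    coords = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
    return build_mst(coords, jitter_scale=0.0)
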