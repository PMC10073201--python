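import numpy as np
import pytest

import phasekit as pk


@pytest.fixture(scope="session")
def fitted():
    """The packaged fitted DVC parameter means."""
    return pk.default_params()


@pytest.fixture(scope="session")
def stable_fp(fitted):
    """The unique stable fixed point of the PD system at s = 1."""
    pts = [fp for fp in pk.fixed_points(fitted, 1.0) if fp.stable]
    assert len(pts) == 1
    return pts[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
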