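import numpy as np
import pytest

from fbconn import ComponentTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ar1(n, phi=0.9, rng=None, ncols=1):
    """Smooth AR(1) series for approximation tests."""
    rng = rng or np.random.default_rng(0)
    eps = rng.standard_normal((n, ncols))
    out = np.empty_like(eps)
    out[0] = eps[0]
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out if ncols > 1 else out[:, 0]


@pytest.fixture
def small_subject(rng):
    """Six-component subject, 400 samples, TR=2 s."""
    vals = ar1(400, phi=0.6, rng=rng, ncols=6)
    return ComponentTimeSeries(values=vals, tr_seconds=2.0, subject_id="s01")
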