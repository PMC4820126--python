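import math

import numpy as np
import pytest

from nsebp import SRM0Params


@pytest.fixture
def params2():
    """tau1 = 2 ms model with kernel-scale threshold (worked examples)."""
    return SRM0Params(tau1=2.0, theta=0.25, A2=10.0, theta_v=0.05)


@pytest.fixture
def params5():
    """tau1 = 5 ms benchmark model."""
    return SRM0Params(tau1=5.0, theta=1.0, theta_v=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def peak_lag2():
    return 2.0 * math.log(2.0)
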