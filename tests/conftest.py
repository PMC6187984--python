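import numpy as np
import pytest

from parcs.simulate import StepModelSpec, mean_profile


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def noiseless_single_step():
    """Deterministic step series: b=0, w=1, c=20, T=100."""
    spec = StepModelSpec(T=100, cps=(20,), weights=((1.0,),))
    return mean_profile(spec)[:, 0]


@pytest.fixture(scope="session")
def noiseless_two_step():
    """Deterministic two-step series: c=(20,60), w=(1,2), T=100."""
    spec = StepModelSpec(T=100, cps=(20, 60), weights=((1.0,), (2.0,)))
    return mean_profile(spec)[:, 0]
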