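import numpy as np
import pytest

from nucleoshift import synthdata


@pytest.fixture
def default_stack():
    """One default two-channel stack with ground truth, shared per test."""
    spec = synthdata.StackSpec(nuclear_fraction=0.30, seed=11)
    nuclear, signal, truth, realized = synthdata.gen_stack(spec)
    return spec, nuclear, signal, truth, realized


@pytest.fixture
def clean_stack():
    """A noiseless, blur-free stack whose mask recovery is exact."""
    spec = synthdata.StackSpec(
        nuclear_fraction=0.30, blur_sigma=0.0, noise_sd=0.0, seed=3
    )
    return (spec, *synthdata.gen_stack(spec))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
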