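import numpy as np
import pytest

from dictmri import synthetic as syn


@pytest.fixture
def phantom64():
    return syn.make_phantom(syn.PhantomSpec(seed=3))


@pytest.fixture
def phantom32():
    return syn.make_phantom(syn.PhantomSpec(height=32, width=32, seed=11))


@pytest.fixture
def sample40(phantom64):
    """Noiseless 40% variable-density acquisition of the 64x64 phantom."""
    mask = syn.make_mask(syn.MaskSpec(sampling_rate=0.4, seed=1), phantom64.shape)
    return syn.simulate_acquisition(phantom64, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
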