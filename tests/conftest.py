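import numpy as np
import pytest

from mwikit import FitConfig, SequenceParams, epg_decay_curve


@pytest.fixture(scope="session")
def seq():
    return SequenceParams()


@pytest.fixture(scope="session")
def cfg():
    return FitConfig()


@pytest.fixture(scope="session")
def two_pool():
    """Factory for noiseless two-pool decays: (mwf, flip, myelin_t2, ie_t2)."""
    def make(mwf=0.15, flip=150.0, myelin_t2=20.0, ie_t2=80.0,
             seq=SequenceParams()):
        return (mwf * epg_decay_curve(myelin_t2, flip, seq)
                + (1.0 - mwf) * epg_decay_curve(ie_t2, flip, seq))
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
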