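import numpy as np
import pytest

from exobci import decoder as dec
from exobci import synth


@pytest.fixture(scope="session")
def small_session():
    """12 trials/class training session with the default clear-ERD params."""
    return synth.generate_training_session(n_per_class=12, seed=7)


@pytest.fixture(scope="session")
def small_windows(small_session):
    rec, trials = small_session
    out = {}
    for pair_name in ("gvn", "gvs"):
        out[pair_name] = dec.epoch_training_windows(rec, trials, dec.PAIRS[pair_name])
    return out


@pytest.fixture(scope="session")
def small_models(small_windows):
    models = {}
    for pair_name, (windows, labels, _) in small_windows.items():
        models[pair_name] = dec.train_decoder(windows, labels, pair_name)
    return models


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
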