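import warnings

import numpy as np
import pytest

from optotheta import synth
from optotheta.io_model import StimProtocol, paired_epochs


@pytest.fixture(scope="session")
def small_session():
    """A compact but complete synthetic session shared across tests."""
    cfg = synth.SynthConfig(seed=42, n_hp_channels=4, n_units_per_region=10,
                            session_length=200.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec, spikes, protocol = synth.generate_session(cfg)
    return cfg, rec, spikes, protocol


@pytest.fixture(scope="session")
def lfp_only_session():
    """One-channel LFP session (no spikes), default 600 s conditions."""
    cfg = synth.SynthConfig(seed=7, n_hp_channels=1, n_ms_channels=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = synth.generate_lfp(cfg)
    return cfg, rec, StimProtocol.default()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_pairs():
    return paired_epochs(StimProtocol.default())
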