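import numpy as np
import pytest

import corallox as cx


@pytest.fixture(scope="session")
def synth_config():
    return cx.SynthConfig(seed=7, n_sequences=40)


@pytest.fixture(scope="session")
def reference(synth_config):
    return cx.make_pseudo_reference(synth_config)


@pytest.fixture(scope="session")
def cox_reference(synth_config):
    return cx.make_cox_reference(synth_config)


@pytest.fixture(scope="session")
def reference_set(reference, cox_reference):
    return cx.ReferenceSet(reference, cox_reference)


@pytest.fixture(scope="session")
def rules(synth_config):
    return cx.default_rule_table(synth_config.layout.coffa_pos)


@pytest.fixture(scope="session")
def small_panel(synth_config):
    """40 synthetic sequences + truth, shared across tests."""
    return cx.generate_panel(synth_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
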