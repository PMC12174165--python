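"""Shared fixtures: packaged model sources and compiled models."""

import pytest

import spikelang as sl
from spikelang.compiler import compile_model


@pytest.fixture(scope="session")
def adex_text():
    return sl.load_model_text("adex_neuron")


@pytest.fixture(scope="session")
def stdp_text():
    return sl.load_model_text("stdp_synapse")


@pytest.fixture(scope="session")
def lif_text():
    return sl.load_model_text("lif_toy")


@pytest.fixture()
def adex_ast(adex_text):
    return sl.parse_model(adex_text, origin="adex_neuron.sl")


@pytest.fixture()
def stdp_ast(stdp_text):
    return sl.parse_model(stdp_text, origin="stdp_synapse.sl")


@pytest.fixture(scope="session")
def adex_model(adex_text):
    return compile_model(adex_text, origin="adex_neuron.sl")


@pytest.fixture(scope="session")
def stdp_model(stdp_text):
    return compile_model(stdp_text, origin="stdp_synapse.sl")


@pytest.fixture(scope="session")
def lif_model(lif_text):
    return compile_model(lif_text, origin="lif_toy.sl")
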