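import pytest

from vertigopop import default_initial_state, default_parameters


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture
def initial_state():
    return default_initial_state()
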