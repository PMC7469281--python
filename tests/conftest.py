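import pytest

from tnfboolnet.model import load_paper_model


@pytest.fixture(scope="session")
def paper_model():
    return load_paper_model()
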