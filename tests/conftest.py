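import pytest

from degencode.stability import predict_table


@pytest.fixture(scope="session")
def predicted():
    """S-rule prediction over the 16 doublets, scored against the
    built-in mitochondrial reference."""
    return predict_table()
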