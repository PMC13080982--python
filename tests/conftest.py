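import pytest

from fgcompress.smiles_text import tokenize


@pytest.fixture
def branch_example():
    """Two-molecule dataset whose best substructure sits inside brackets."""
    return [tokenize(s) for s in ["CCN(O)", "CN(O)CC"]]


@pytest.fixture
def carbonyl_trio():
    """Three molecules sharing the (=O) fragment."""
    return [tokenize(s) for s in ["C(=O)", "N(=O)", "S(=O)"]]
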