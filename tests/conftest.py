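import pytest

from cyp75.simulate import make_paper_panel, make_reference
from cyp75.sequences import translate


@pytest.fixture(scope="session")
def reference():
    return make_reference()[0]


@pytest.fixture(scope="session")
def domain_map():
    return make_reference()[1]


@pytest.fixture(scope="session")
def ref_protein(reference):
    return translate(reference)


@pytest.fixture(scope="session")
def paper_panel():
    """(panel, truth): the nine-haplotype study panel with ground truth."""
    return make_paper_panel()


@pytest.fixture(scope="session")
def panel_by_id(paper_panel):
    panel, _ = paper_panel
    return {hap.id: hap for hap in panel}
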