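import pytest

from mtmine import EvidenceLexicon, load_reference


@pytest.fixture(scope="session")
def ref_cat():
    return load_reference()


@pytest.fixture(scope="session")
def reference(ref_cat):
    return ref_cat[0]


@pytest.fixture(scope="session")
def catalogue(ref_cat):
    return ref_cat[1]


@pytest.fixture(scope="session")
def lexicon():
    return EvidenceLexicon.default()
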