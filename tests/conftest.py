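import pytest

from repeatscope import load_default_catalog, get_locus


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def fgf14(catalog):
    return get_locus(catalog, "FGF14")


@pytest.fixture(scope="session")
def rfc1(catalog):
    return get_locus(catalog, "RFC1")


@pytest.fixture(scope="session")
def fmr1(catalog):
    return get_locus(catalog, "FMR1")
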