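import pytest

from clonesim.cut import default_registry
from clonesim.join import default_sites
from clonesim.fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def sites():
    return default_sites()


@pytest.fixture(scope="session")
def toy_plasmid():
    return generate_fixture(FixtureSpec("toy_plasmid", seed=1))


@pytest.fixture(scope="session")
def golden_gate():
    return generate_fixture(FixtureSpec("golden_gate_set", seed=7, params={"n_inserts": 3}))


@pytest.fixture(scope="session")
def lox_plasmid():
    return generate_fixture(FixtureSpec("lox_substrate", seed=3,
                                        params={"gap": 1000, "rest": 600}))


@pytest.fixture(scope="session")
def att_pair():
    return generate_fixture(FixtureSpec("att_substrate_pair", seed=5))


@pytest.fixture(scope="session")
def genomic_locus():
    return generate_fixture(FixtureSpec("genomic_locus", seed=9))
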