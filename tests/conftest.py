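import pytest

from tapkit.config import RunConfig
from tapkit.fixtures import FixtureSpec, make_mini_fv, make_peptide
from tapkit.surface import load_max_sasa_table, run_sasa_pipeline


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def max_table():
    return load_max_sasa_table()


@pytest.fixture(scope="session")
def mini_fv():
    """Deterministic two-chain mini-Fv with designed CDR lengths 8/8/10 + 6/3/9."""
    return make_mini_fv(FixtureSpec(seed=11, id="mini"))


@pytest.fixture(scope="session")
def mini_sasa(mini_fv, config, max_table):
    """(SasaResult, exposure map) for the session mini-Fv."""
    return run_sasa_pipeline(mini_fv, config, max_table)


@pytest.fixture(scope="session")
def decapeptide():
    """10-residue extended peptide used by the SASA oracles."""
    return make_peptide("ACDEFGHIKL", structure_id="deca")
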