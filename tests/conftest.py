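import pytest

from neoforge import mhcrank, proteodb, synthdata
from neoforge.synthdata import SimulationConfig


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(
        seed=11, n_transcripts=20, cds_length_range=(150, 300),
        n_missense=8, n_frameshift=3,
    )


@pytest.fixture(scope="session")
def transcripts(sim_config):
    return synthdata.gen_reference(sim_config)


@pytest.fixture(scope="session")
def variants(sim_config, transcripts):
    return synthdata.gen_variants(transcripts, sim_config)


@pytest.fixture(scope="session")
def db_entries(transcripts, variants):
    return proteodb.build_database(transcripts, variants, "tumor")


@pytest.fixture(scope="session")
def rank_model():
    return mhcrank.RankModel(seed=7)
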