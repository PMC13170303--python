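import pytest

from rdnasat.records import SequenceRecord
from rdnasat.simulate import SimConfig, make_genome

# a compact locus (2.6 kb units) so module tests stay fast; the full-size
# defaults are exercised by the acceptance tests
SMALL_KW = dict(
    gene_lengths={"18S": 400, "5.8S": 120, "28S": 600},
    its_lengths=(120, 150),
    ets_lengths=(200, 200),
    igs_length=800,
    sat_copies_per_igs=6,
    units_per_array=(3, 5),
    inter_array_gap=9_000,
    flank_background=3_000,
    read_depth=200,
)

SMALL_MAX_GAP = 4_000
SMALL_FLANK = 2_200


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=42, **SMALL_KW)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return make_genome(small_cfg)


@pytest.fixture(scope="session")
def small_refs(small_sim):
    return {g: small_sim.refs[g] for g in ("18S", "5.8S", "28S")}


@pytest.fixture()
def seq_factory():
    def make(seq, sid="seq"):
        return SequenceRecord(sid, seq)

    return make
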