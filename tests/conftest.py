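import pytest

from bcrep.clustering import cluster_repertoire
from bcrep.records import RepertoireSample, SequenceRecord
from bcrep.simulate import make_germline_db, sample_reads, simulate_repertoire


@pytest.fixture(scope="session")
def germline():
    return make_germline_db(20, 4, seed=11)


@pytest.fixture
def rec():
    """Factory for hand-built sequence records with sensible defaults."""

    def _make(i=0, cdr3="CARDYWGQGTLVW", v="IGHV1-1", j="IGHJ1", mut=0,
              iso="IgG", sub="IgG1", mism=0, clen=100):
        return SequenceRecord(
            id=f"seq{i}", v_gene=v, j_gene=j, cdr3_aa=cdr3,
            v_mutation_count=mut, isotype=iso, subclass=sub,
            c_region_mismatches=mism, c_region_length=clen,
        )

    return _make


@pytest.fixture
def make_sample(rec):
    def _make(records, participant="P01", day=0, isotype="IgG", replicate="rep1"):
        return RepertoireSample(
            participant=participant, day=day, isotype=isotype,
            replicate=replicate, records=records,
        )

    return _make


@pytest.fixture(scope="session")
def bimodal_sample(germline):
    """A sequenced sample with the expected bimodal CDR3 distance structure."""
    rep = simulate_repertoire(germline, 400, abundance_shape=1.2, seed=21)
    return sample_reads(rep, 1200, 2000, seed=22).to_sample()


@pytest.fixture(scope="session")
def bimodal_clusters(bimodal_sample):
    return cluster_repertoire(bimodal_sample, k=12)
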