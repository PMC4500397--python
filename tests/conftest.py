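import pytest

from gvcompare.orf_annotation import annotate
from gvcompare.synthetic_data import fixture_family, simulate_annotated_genome, fixture_config


@pytest.fixture(scope="session")
def family():
    """Ancestor + two descendants with planted truth (fixed seed)."""
    return fixture_family()


@pytest.fixture(scope="session")
def sim_pair(family):
    """(genome, truth) of the ancestor."""
    return family[0]


@pytest.fixture(scope="session")
def sim_annotation(sim_pair):
    genome, _ = sim_pair
    return annotate(genome)


@pytest.fixture(scope="session")
def family_annotations(family):
    return [annotate(g) for g, _ in family]


def annotation_id_map(truth, annotation):
    """planted ORF id -> annotation orf_id, matched by exact span."""
    key = {(r.strand, r.fwd_start, r.length_nt): r.orf_id for r in annotation.orfs}
    return {r.orf_id: key[(r.strand, r.fwd_start, r.length_nt)]
            for r in truth.orfs
            if (r.strand, r.fwd_start, r.length_nt) in key}
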