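import numpy as np
import pytest

from sigpath import SimConfig, generate
from sigpath.io import AnnotationMap, HomologMap, PathwayMembership, PPINetwork
from sigpath.pipeline import labeled_records, training_assignment


@pytest.fixture
def tiny_membership() -> PathwayMembership:
    return PathwayMembership.from_pathways(
        {
            "TCR": {"P1", "P2", "P3"},
            "BCR": {"P3", "P4"},
            "Wnt": {"P5"},
        }
    )


@pytest.fixture
def tiny_annotations() -> AnnotationMap:
    amap = AnnotationMap()
    for acc, terms in {
        "P1": {"GO:0000001", "GO:0000002"},
        "P2": {"GO:0000001"},
        "P3": {"GO:0000002", "GO:0000003"},
        "P4": {"GO:0000003"},
        "P5": {"GO:0000004"},
        "H1": {"GO:0000001", "GO:0000005"},
    }.items():
        for t in terms:
            amap.add(acc, t)
    return amap


@pytest.fixture
def tiny_network() -> PPINetwork:
    net = PPINetwork()
    for a, b in [("P1", "P2"), ("P2", "P3"), ("P3", "X1"), ("X1", "X2"), ("P5", "X2")]:
        net.add_edge(a, b)
    return net


@pytest.fixture(scope="session")
def small_corpus():
    """Strongly separable small corpus shared across slow-ish tests."""
    cfg = SimConfig(
        n_pathways=3,
        n_proteins_per_pathway=25,
        n_background_proteins=60,
        n_signature_terms=12,
        n_background_terms=40,
        seed=101,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_corpus_training(small_corpus):
    """(records, assignment) for the small corpus, negatives included."""
    ann = small_corpus.annotations.merged(small_corpus.homolog_annotations)
    assignment = training_assignment(ann, small_corpus.homologs, small_corpus.membership, seed=5)
    records = labeled_records(ann, small_corpus.homologs, assignment)
    return records, assignment


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
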