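"""Synthetic corpus generator with planted pathway structure.

The generator emulates the statistical structure the method assumes: each
pathway owns a disjoint block of signature GO terms; pathway proteins carry
their pathways' signatures with probability ``p_signal`` plus sparse
background terms; a fraction of signaling proteins belong to a second
pathway (multi-membership); each protein has one synthetic homolog whose
annotation set is a noisy copy of the target set (per-term dropout plus
random extra terms); and the PPI network has elevated within-pathway edge
density. Background proteins annotated only with background terms serve as
the negative-class candidate pool.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import (
    AnnotationMap,
    HomologMap,
    PathwayMembership,
    PPINetwork,
    read_annotations,
    read_blast_tabular,
    read_pathway_membership,
    read_ppi_edges,
    write_annotations,
    write_blast_tabular,
    write_pathway_membership,
    write_ppi_edges,
)
from .labels import LabelAssignment, assemble_labels

_PROBABILITY_FIELDS = (
    "p_signal",
    "p_noise_term",
    "p_multilabel",
    "homolog_dropout",
    "homolog_noise",
    "ppi_within",
    "ppi_between",
)
_COUNT_FIELDS = (
    "n_pathways",
    "n_proteins_per_pathway",
    "n_background_proteins",
    "n_signature_terms",
    "n_background_terms",
)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults define the standard study conditions.

    Six pathways of 100 proteins with 40 signature terms each, 90% signature
    annotation probability, 2% per-background-term noise, 20% dual
    membership, homolog dropout 0.2 — a strongly but not perfectly
    separable regime with a realistic noisy transfer channel.
    """

    n_pathways: int = 6
    n_proteins_per_pathway: int = 100
    n_heldout_per_pathway: int = 0
    n_background_proteins: int = 200
    n_signature_terms: int = 40
    n_background_terms: int = 100
    p_signal: float = 0.9
    p_noise_term: float = 0.02
    p_multilabel: float = 0.2
    homolog_dropout: float = 0.2
    homolog_noise: float = 0.02
    ppi_within: float = 0.1
    ppi_between: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in _COUNT_FIELDS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_heldout_per_pathway < 0:
            raise ValueError("n_heldout_per_pathway must be >= 0")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticCorpus:
    """All four pipeline inputs plus the planted ground truth."""

    annotations: AnnotationMap
    homolog_annotations: AnnotationMap
    homologs: HomologMap
    membership: PathwayMembership
    network: PPINetwork
    truth: LabelAssignment
    background_proteins: set[str] = field(default_factory=set)
    #: planted labels of held-out novel components (annotated but absent
    #: from the membership table; the prediction stage should find them)
    heldout_truth: dict[str, frozenset[int]] = field(default_factory=dict)

    @property
    def universe(self) -> set[str]:
        return set(self.annotations.entries)


def _go_id(i: int) -> str:
    return f"GO:{i:07d}"


def generate(config: SimConfig) -> SyntheticCorpus:
    """Draw a complete synthetic corpus from the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    d = config.n_pathways

    # disjoint signature blocks, then background terms
    signature_terms = [
        [_go_id(p * config.n_signature_terms + t + 1) for t in range(config.n_signature_terms)]
        for p in range(d)
    ]
    bg_start = d * config.n_signature_terms
    background_terms = [_go_id(bg_start + t + 1) for t in range(config.n_background_terms)]

    pathway_names = [f"PW{p + 1:02d}" for p in range(d)]
    n_signal = d * (config.n_proteins_per_pathway + config.n_heldout_per_pathway)
    width = len(str(n_signal + config.n_background_proteins))

    membership_sets: dict[str, set[str]] = {name: set() for name in pathway_names}
    # pathway blocks used for PPI density, including held-out novel components
    density_sets: dict[str, set[str]] = {name: set() for name in pathway_names}
    annotations = AnnotationMap()
    homolog_annotations = AnnotationMap()
    homologs = HomologMap(evalue_cutoff=10.0)
    heldout_truth: dict[str, frozenset[int]] = {}

    def _draw_signaling(acc: str, p: int) -> set[int]:
        pathways = {p}
        if d > 1 and rng.random() < config.p_multilabel:
            second = int(rng.integers(d - 1))
            if second >= p:
                second += 1
            pathways.add(second)
        target: set[str] = set()
        for q in pathways:
            density_sets[pathway_names[q]].add(acc)
            for term in signature_terms[q]:
                if rng.random() < config.p_signal:
                    target.add(term)
        for term in background_terms:
            if rng.random() < config.p_noise_term:
                target.add(term)
        _store_protein(
            acc, target, config, rng, background_terms, annotations,
            homolog_annotations, homologs,
        )
        return pathways

    counter = 0
    for p in range(d):
        for _ in range(config.n_proteins_per_pathway):
            counter += 1
            acc = f"P{counter:0{width}d}"
            for q in _draw_signaling(acc, p):
                membership_sets[pathway_names[q]].add(acc)

    for p in range(d):
        for _ in range(config.n_heldout_per_pathway):
            counter += 1
            acc = f"N{counter:0{width}d}"
            pathways = _draw_signaling(acc, p)
            heldout_truth[acc] = frozenset(q + 1 for q in pathways)

    background_proteins: set[str] = set()
    for _ in range(config.n_background_proteins):
        counter += 1
        acc = f"B{counter:0{width}d}"
        background_proteins.add(acc)
        # guarantee one background term so the record passes the removal rule
        target = {background_terms[int(rng.integers(len(background_terms)))]}
        for term in background_terms:
            if rng.random() < config.p_noise_term:
                target.add(term)
        _store_protein(
            acc, target, config, rng, background_terms, annotations,
            homolog_annotations, homologs,
        )

    membership = PathwayMembership.from_pathways(membership_sets)
    truth = assemble_labels(membership)

    network = _draw_network(
        sorted(annotations.entries), density_sets, config, rng
    )
    return SyntheticCorpus(
        annotations=annotations,
        homolog_annotations=homolog_annotations,
        homologs=homologs,
        membership=membership,
        network=network,
        truth=truth,
        background_proteins=background_proteins,
        heldout_truth=heldout_truth,
    )


def _store_protein(
    acc: str,
    target: set[str],
    config: SimConfig,
    rng: np.random.Generator,
    background_terms: list[str],
    annotations: AnnotationMap,
    homolog_annotations: AnnotationMap,
    homologs: HomologMap,
) -> None:
    for term in sorted(target):
        annotations.add(acc, term)
    homolog_acc = f"H_{acc}"
    homolog_terms = {t for t in target if rng.random() >= config.homolog_dropout}
    for term in background_terms:
        if rng.random() < config.homolog_noise:
            homolog_terms.add(term)
    for term in sorted(homolog_terms):
        homolog_annotations.add(homolog_acc, term)
    homologs.entries[acc] = {homolog_acc}


def _draw_network(
    proteins: list[str],
    membership_sets: dict[str, set[str]],
    config: SimConfig,
    rng: np.random.Generator,
) -> PPINetwork:
    index = {acc: i for i, acc in enumerate(proteins)}
    n = len(proteins)
    prob = np.full((n, n), config.ppi_between)
    for members in membership_sets.values():
        idx = np.fromiter((index[m] for m in members), dtype=int)
        prob[np.ix_(idx, idx)] = config.ppi_within
    draw = rng.random((n, n))
    iu, ju = np.triu_indices(n, k=1)
    hit = draw[iu, ju] < prob[iu, ju]
    net = PPINetwork()
    for i, j in zip(iu[hit], ju[hit]):
        net.add_edge(proteins[i], proteins[j])
    return net


def export(corpus: SyntheticCorpus, directory: str | Path) -> dict[str, Path]:
    """Write the corpus as the four standard-format files.

    Target and homolog annotations go into one annotation TSV (homolog
    subjects are ordinary annotated proteins); homology hits are written as
    BLAST tabular rows.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": directory / "annotations.tsv",
        "homologs": directory / "homologs.tsv",
        "membership": directory / "membership.tsv",
        "ppi": directory / "ppi.tsv",
    }
    write_annotations(corpus.annotations.merged(corpus.homolog_annotations), paths["annotations"])
    write_blast_tabular(corpus.homologs, paths["homologs"])
    write_pathway_membership(corpus.membership, paths["membership"])
    write_ppi_edges(corpus.network, paths["ppi"])
    return paths


def load(directory: str | Path) -> tuple[AnnotationMap, HomologMap, PathwayMembership, PPINetwork]:
    """Read back the four files written by :func:`export`."""
    directory = Path(directory)
    return (
        read_annotations(directory / "annotations.tsv"),
        read_blast_tabular(directory / "homologs.tsv"),
        read_pathway_membership(directory / "membership.tsv"),
        read_ppi_edges(directory / "ppi.tsv"),
    )
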