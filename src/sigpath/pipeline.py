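"""End-to-end orchestration of the reconstruction pipeline.

The stages: assemble labeled records from annotations + homology hits +
pathway membership, add a seeded negative class, train the multi-instance
label-powerset model on all labeled proteins, predict pathway labels for
candidate proteins (the annotated universe minus training proteins), link
predictions into pathways through the experimental PPI network, and compute
cross-talk matrices and GO enrichment tables for the merged
experimental + predicted pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classifier import (
    KernelParams,
    MultiInstancePathwayModel,
    PredictionResult,
)
from .crosstalk import CrosstalkMatrix, crosstalk_matrix
from .enrichment import EnrichmentTable, enrichment_table
from .features import InstanceKind, ProteinRecord, build_records, filter_unannotated
from .io import AnnotationMap, HomologMap, PathwayMembership, PPINetwork
from .labels import LabelAssignment, assemble_labels, sample_negative_class
from .reconstruction import PathwayReconstruction, induced_edges, link_predictions


def homolog_subjects(homologs: HomologMap) -> set[str]:
    out: set[str] = set()
    for subjects in homologs.entries.values():
        out |= subjects
    return out


def training_assignment(
    annotations: AnnotationMap,
    homologs: HomologMap,
    membership: PathwayMembership,
    seed: int,
    negative_universe: set[str] | None = None,
) -> LabelAssignment:
    """Pathway labels plus a seeded negative class.

    Negative candidates default to annotated proteins that are neither
    pathway members nor homolog subjects (homolog subjects exist only as
    annotation carriers for the transfer channel, not as classifiable
    proteins). Pass ``negative_universe`` to sample from a curated pool
    instead, e.g. proteins known not to signal.
    """
    assignment = assemble_labels(membership)
    if negative_universe is None:
        negative_universe = set(annotations.entries) - homolog_subjects(homologs)
    return sample_negative_class(negative_universe, assignment, seed)


def labeled_records(
    annotations: AnnotationMap,
    homologs: HomologMap,
    assignment: LabelAssignment,
    homolog_annotations: AnnotationMap | None = None,
) -> list[ProteinRecord]:
    """Protein records for every labeled accession, removal rule applied."""
    records = build_records(
        sorted(assignment.labels_of), annotations, homologs, homolog_annotations
    )
    return filter_unannotated(records)


def candidate_records(
    annotations: AnnotationMap,
    homologs: HomologMap,
    assignment: LabelAssignment,
    homolog_annotations: AnnotationMap | None = None,
) -> list[ProteinRecord]:
    """Records for the prediction universe: annotated proteins that are
    neither training proteins nor homolog subjects."""
    universe = set(annotations.entries) - set(assignment.labels_of) - homolog_subjects(homologs)
    records = build_records(sorted(universe), annotations, homologs, homolog_annotations)
    return filter_unannotated(records)


def predicted_components(
    results: list[PredictionResult],
    membership: PathwayMembership,
    negative_label: int,
) -> dict[InstanceKind, dict[str, set[str]]]:
    """Per instance kind, pathway name -> predicted novel component set."""
    by_kind: dict[InstanceKind, dict[str, set[str]]] = {}
    names = {idx: name for name, idx in membership.label_index.items()}
    for result in results:
        for kind, labels in result.by_kind.items():
            table = by_kind.setdefault(kind, {name: set() for name in membership.pathways})
            for label in labels:
                if label == negative_label:
                    continue
                table[names[label]].add(result.accession)
    return by_kind


@dataclass
class ReconstructionRun:
    """Outputs of one full predict-link-crosstalk-enrich run."""

    assignment: LabelAssignment
    predictions: list[PredictionResult]
    components: dict[InstanceKind, dict[str, set[str]]]
    reconstructions: dict[InstanceKind, dict[str, PathwayReconstruction]]
    ctr_components: dict[InstanceKind, CrosstalkMatrix] = field(default_factory=dict)
    ctr_ppis: dict[InstanceKind, CrosstalkMatrix] = field(default_factory=dict)
    enrichment: dict[InstanceKind, dict[str, EnrichmentTable]] = field(default_factory=dict)


def run_reconstruction(
    annotations: AnnotationMap,
    homologs: HomologMap,
    membership: PathwayMembership,
    network: PPINetwork,
    seed: int = 0,
    params: KernelParams | None = None,
    homolog_annotations: AnnotationMap | None = None,
    negative_universe: set[str] | None = None,
) -> ReconstructionRun:
    """Train on all labeled data, predict candidates, link and map cross-talks."""
    params = params or KernelParams()
    assignment = training_assignment(
        annotations, homologs, membership, seed, negative_universe=negative_universe
    )
    train_recs = labeled_records(annotations, homologs, assignment, homolog_annotations)
    candidates = candidate_records(annotations, homologs, assignment, homolog_annotations)
    if not candidates:
        raise ValueError("empty candidate set: nothing to predict")

    model = MultiInstancePathwayModel(gamma=params.gamma, C=params.cost)
    model.fit(train_recs, assignment)
    predictions = model.predict(candidates)
    components = predicted_components(predictions, membership, assignment.negative_label)

    reconstructions: dict[InstanceKind, dict[str, PathwayReconstruction]] = {}
    ctr_comp: dict[InstanceKind, CrosstalkMatrix] = {}
    ctr_ppi: dict[InstanceKind, CrosstalkMatrix] = {}
    enrich: dict[InstanceKind, dict[str, EnrichmentTable]] = {}
    for kind, table in components.items():
        recons = {
            name: link_predictions(
                membership.pathways[name], table[name], network, pathway=name
            )
            for name in membership.pathways
        }
        reconstructions[kind] = recons
        merged_members = {
            name: membership.pathways[name] | table[name] for name in membership.pathways
        }
        merged_edges = {
            name: induced_edges(membership.pathways[name], network) | recons[name].novel_ppis
            for name in membership.pathways
        }
        if len(merged_members) >= 2:
            ctr_comp[kind] = crosstalk_matrix(merged_members, mode="components")
            ctr_ppi[kind] = crosstalk_matrix(merged_edges, mode="ppis")
        enrich[kind] = {
            name: enrichment_table(table[name], annotations)
            for name in membership.pathways
            if table[name]
        }
    return ReconstructionRun(
        assignment=assignment,
        predictions=predictions,
        components=components,
        reconstructions=reconstructions,
        ctr_components=ctr_comp,
        ctr_ppis=ctr_ppi,
        enrichment=enrich,
    )
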