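"""Link predicted signaling components into pathways via experimental PPIs.

A predicted component joins a pathway's reconstruction when an experimental
interaction connects it to the pathway. Two kinds of novel signaling PPIs
arise: (1) interactions between a predicted component and a known component,
and (2) interactions between two predicted components. "Novel" means the
interaction is newly treated as part of the pathway, not newly predicted —
every novel edge exists verbatim in the input network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .io import PPINetwork

Edge = tuple[str, str]


@dataclass
class PathwayReconstruction:
    """Known and predicted components of one pathway plus derived novel PPIs."""

    pathway: str
    known_components: set[str]
    predicted_components: set[str]
    novel_ppis_kind1: set[Edge] = field(default_factory=set)  # predicted <-> known
    novel_ppis_kind2: set[Edge] = field(default_factory=set)  # predicted <-> predicted
    linked_components: set[str] = field(default_factory=set)

    @property
    def novel_ppis(self) -> set[Edge]:
        return self.novel_ppis_kind1 | self.novel_ppis_kind2


def link_predictions(
    known: Iterable[str],
    predicted: Iterable[str],
    network: PPINetwork,
    pathway: str = "",
) -> PathwayReconstruction:
    """Classify network edges incident to predicted components.

    ``known`` and ``predicted`` must be disjoint: the prediction step only
    scores candidates outside the training components, so an overlap signals
    an upstream bookkeeping error.
    """
    known = set(known)
    predicted = set(predicted)
    overlap = known & predicted
    if overlap:
        raise ValueError(
            f"known and predicted components overlap: {sorted(overlap)[:5]}"
        )
    recon = PathwayReconstruction(
        pathway=pathway, known_components=known, predicted_components=predicted
    )
    for a, b in network.edges:
        a_pred, b_pred = a in predicted, b in predicted
        if not (a_pred or b_pred):
            continue
        if a_pred and b_pred:
            recon.novel_ppis_kind2.add((a, b))
        elif (a_pred and b in known) or (b_pred and a in known):
            recon.novel_ppis_kind1.add((a, b))
    for a, b in recon.novel_ppis:
        if a in predicted:
            recon.linked_components.add(a)
        if b in predicted:
            recon.linked_components.add(b)
    return recon


def induced_edges(members: Iterable[str], network: PPINetwork) -> set[Edge]:
    """Experimental signaling PPIs of a pathway: edges with both endpoints
    among its members."""
    members = set(members)
    return {(a, b) for a, b in network.edges if a in members and b in members}


def reconstructed_edge_set(
    recon: PathwayReconstruction, experimental_edges: Iterable[Edge]
) -> set[Edge]:
    """Union of a pathway's experimental edges with its novel signaling PPIs."""
    return set(experimental_edges) | recon.novel_ppis
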