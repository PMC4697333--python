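"""Static cross-talk maps between signaling pathways.

Two pathways communicate via shared signaling components and shared
signaling PPIs. The cross-talk ratio (CTR) of two element sets A and B is
their Jaccard overlap |A ∩ B| / |A ∪ B| — applied to component accession
sets (CTR over components) or to canonical PPI edge sets (CTR over
signaling PPIs). Values are kept in [0, 1] internally; multiply by 100 only
at presentation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, TypeVar

import numpy as np
import pandas as pd

T = TypeVar("T", bound=Hashable)


def ctr(set_a: Iterable[T], set_b: Iterable[T]) -> float:
    """Cross-talk ratio: Jaccard overlap of two element sets.

    Defined as 0 when both sets are empty (the 0/0 convention), 1 iff the
    sets are equal and non-empty.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def common_elements(set_a: Iterable[T], set_b: Iterable[T]) -> list[T]:
    """Shared elements of two pathways, in deterministic sorted order."""
    return sorted(set(set_a) & set(set_b))


@dataclass
class CrosstalkMatrix:
    """Symmetric pathway-by-pathway matrix of cross-talk ratios."""

    pathway_order: list[str]
    values: np.ndarray
    mode: str  # "components" | "ppis"

    def at(self, a: str, b: str) -> float:
        i, j = self.pathway_order.index(a), self.pathway_order.index(b)
        return float(self.values[i, j])

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        vals = self.values * 100.0 if percent else self.values
        return pd.DataFrame(vals, index=self.pathway_order, columns=self.pathway_order)


def crosstalk_matrix(
    pathways: Mapping[str, Iterable[T]], mode: str = "components"
) -> CrosstalkMatrix:
    """Pairwise cross-talk ratios for a collection of pathway element sets.

    ``mode`` records whether the element sets are component accessions or
    canonical PPI edges; the arithmetic is identical.
    """
    if mode not in ("components", "ppis"):
        raise ValueError(f"unknown crosstalk mode {mode!r}")
    if len(pathways) < 2:
        raise ValueError("need at least 2 pathways for a cross-talk matrix")
    order = sorted(pathways)
    sets = [set(pathways[name]) for name in order]
    n = len(order)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = ctr(sets[i], sets[j])
    return CrosstalkMatrix(pathway_order=order, values=values, mode=mode)
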