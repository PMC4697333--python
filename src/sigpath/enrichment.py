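"""Proportion-based GO enrichment of predicted component sets.

For a set of proteins, each GO term's enrichment is the percentage of the
set annotated with that term — a raw proportion over the analyzed set, not
a hypergeometric test against a background. Unannotated proteins stay in
the denominator. Tables can be restricted to one ontology aspect and are
sorted by percentage descending with ties broken by term id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io import AnnotationMap


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    aspect: str | None
    count: int
    percent: float


@dataclass
class EnrichmentTable:
    """Sorted per-term counts and percentages over one protein set."""

    rows: list[EnrichmentRow]
    denominator: int

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.term, r.aspect or "", r.count, r.percent) for r in self.rows],
            columns=["term", "aspect", "count", "percent"],
        )


def enrichment_table(
    proteins: Iterable[str],
    annotations: AnnotationMap,
    aspect: str | None = None,
) -> EnrichmentTable:
    """Per-term annotation proportions over a protein set.

    Only terms annotating at least one input protein appear. When ``aspect``
    is given, terms of other (or unknown) aspects are excluded.
    """
    proteins = set(proteins)
    if not proteins:
        raise ValueError("empty protein set")
    counts: dict[str, int] = {}
    for acc in proteins:
        for term in annotations.terms_of(acc):
            if aspect is not None and (annotations.aspect or {}).get(term) != aspect:
                continue
            counts[term] = counts.get(term, 0) + 1
    n = len(proteins)
    rows = [
        EnrichmentRow(
            term=term,
            aspect=(annotations.aspect or {}).get(term),
            count=c,
            percent=100.0 * c / n,
        )
        for term, c in counts.items()
    ]
    rows.sort(key=lambda r: (-r.percent, r.term))
    return EnrichmentTable(rows=rows, denominator=n)


def top_k(table: EnrichmentTable, k: int = 10) -> EnrichmentTable:
    """Leading ``k`` rows of the sorted table (fewer if the table is shorter)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return EnrichmentTable(rows=table.rows[:k], denominator=table.denominator)
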