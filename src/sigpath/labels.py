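"""Multi-label assignments, the negative "others" class, and the
label-combination (label powerset) codebook.

Pathway classes are numbered ``1..d``; the reserved negative class is
``d + 1`` and never co-occurs with a pathway label. The label-combination
method maps every distinct label set observed in training to one integer
code so that a single multi-class learner handles the whole multi-label
problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io import PathwayMembership

logger = logging.getLogger(__name__)

LabelSet = frozenset[int]


@dataclass
class LabelAssignment:
    """Accession -> non-empty set of integer labels in ``1..d`` or ``{d+1}``."""

    labels_of: dict[str, LabelSet] = field(default_factory=dict)
    d: int = 0

    @property
    def negative_label(self) -> int:
        return self.d + 1

    @property
    def n_classes(self) -> int:
        """Total classes including the negative class."""
        return self.d + 1

    def class_sizes(self) -> dict[int, int]:
        """Number of proteins carrying each pathway label (1..d)."""
        sizes = {j: 0 for j in range(1, self.d + 1)}
        for labels in self.labels_of.values():
            for j in labels:
                if j <= self.d:
                    sizes[j] += 1
        return sizes

    def validate(self) -> None:
        neg = self.negative_label
        for acc, labels in self.labels_of.items():
            if not labels:
                raise ValueError(f"empty label set for {acc!r}")
            if neg in labels and len(labels) > 1:
                raise ValueError(f"negative label co-occurs with pathway labels for {acc!r}")


def assemble_labels(membership: PathwayMembership) -> LabelAssignment:
    """Invert a pathway membership table into per-protein label sets."""
    if not membership.pathways:
        raise ValueError("empty pathway membership")
    labels: dict[str, set[int]] = {}
    for name, members in membership.pathways.items():
        idx = membership.label_index[name]
        for acc in members:
            labels.setdefault(acc, set()).add(idx)
    return LabelAssignment(
        labels_of={acc: frozenset(v) for acc, v in labels.items()},
        d=membership.d,
    )


def sample_negative_class(
    universe: Iterable[str], assignment: LabelAssignment, seed: int
) -> LabelAssignment:
    """Add a seeded random negative class to an assignment.

    Negatives are drawn without replacement from ``universe`` minus the
    pathway members. The sample size equals the size of the largest pathway
    class, which caps class imbalance from the vast non-signaling proteome;
    when the candidate pool is smaller, the whole pool is taken and a
    warning is logged.
    """
    pool = sorted(set(universe) - set(assignment.labels_of))
    if not pool:
        raise ValueError("no negative-class candidates outside the pathway members")
    sizes = assignment.class_sizes()
    n = max(sizes.values()) if sizes else 0
    if len(pool) < n:
        logger.warning(
            "negative-class pool (%d) smaller than requested size (%d); taking all",
            len(pool),
            n,
        )
        chosen = pool
    else:
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(pool, size=n, replace=False).tolist())
    negative = frozenset({assignment.negative_label})
    labels = dict(assignment.labels_of)
    for acc in chosen:
        labels[acc] = negative
    return LabelAssignment(labels_of=labels, d=assignment.d)


@dataclass(frozen=True)
class CombinationCodebook:
    """Bijection between observed label sets and consecutive integer codes.

    Codes start at 1 and are assigned in lexicographic order of the sorted
    label tuples, so the encoding is deterministic across runs. Only
    combinations observed in training exist; a classifier over the codes can
    therefore never emit an unseen combination.
    """

    combo_to_code: dict[LabelSet, int]
    code_to_combo: dict[int, LabelSet]

    def __len__(self) -> int:
        return len(self.combo_to_code)

    def encode(self, labels: Iterable[int]) -> int:
        key = frozenset(labels)
        try:
            return self.combo_to_code[key]
        except KeyError:
            raise KeyError(f"label combination {sorted(key)} not observed in training") from None

    def decode(self, code: int) -> LabelSet:
        try:
            return self.code_to_combo[code]
        except KeyError:
            raise KeyError(f"unknown combination code {code}") from None


def encode_combinations(assignment: LabelAssignment | Mapping[str, LabelSet]) -> CombinationCodebook:
    """Build the label-combination codebook from observed label sets."""
    labels_of = assignment.labels_of if isinstance(assignment, LabelAssignment) else assignment
    if not labels_of:
        raise ValueError("empty label assignment")
    combos = sorted({frozenset(v) for v in labels_of.values()}, key=lambda s: tuple(sorted(s)))
    combo_to_code = {combo: i + 1 for i, combo in enumerate(combos)}
    return CombinationCodebook(
        combo_to_code=combo_to_code,
        code_to_combo={c: combo for combo, c in combo_to_code.items()},
    )


def decode_combination(code: int, codebook: CombinationCodebook) -> LabelSet:
    """Inverse of the codebook encoding; raises on unknown codes."""
    return codebook.decode(code)
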