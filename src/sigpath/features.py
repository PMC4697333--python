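"""Binary GO feature vectors for the target and homolog instances.

Every protein is described by up to two instances over one shared GO-term
vocabulary: the *target* instance encodes the protein's own annotations and
the *homolog* instance encodes the pooled annotations of its sequence
homologs (the knowledge-transfer channel). The vocabulary is the union of
both term sets over the training proteins; a component of an instance vector
is 1 exactly when the corresponding term belongs to the chosen term set.

Proteins annotated in neither channel carry no usable signal and are removed
before training (the removal rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AnnotationMap, HomologMap

InstanceKind = Literal["target", "homolog"]
INSTANCE_KINDS: tuple[InstanceKind, ...] = ("target", "homolog")


@dataclass
class ProteinRecord:
    """One protein with its own GO terms and its homologs' pooled GO terms."""

    accession: str
    target_terms: set[str] = field(default_factory=set)
    homolog_terms: set[str] = field(default_factory=set)

    def terms(self, kind: InstanceKind) -> set[str]:
        if kind == "target":
            return self.target_terms
        if kind == "homolog":
            return self.homolog_terms
        raise ValueError(f"unknown instance kind {kind!r}")

    @property
    def is_annotated(self) -> bool:
        return bool(self.target_terms or self.homolog_terms)


@dataclass(frozen=True)
class GOVocabulary:
    """Ordered GO-term vocabulary shared by all instances of a dataset."""

    terms: tuple[str, ...]
    index: dict[str, int]

    @classmethod
    def from_terms(cls, terms: Iterable[str]) -> "GOVocabulary":
        ordered = tuple(sorted(set(terms)))
        return cls(terms=ordered, index={t: k for k, t in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index


@dataclass
class InstanceVector:
    """Binary feature vector of one instance, tagged with its kind."""

    accession: str
    kind: InstanceKind
    bits: np.ndarray  # shape (|vocabulary|,), dtype uint8

    def one_terms(self, vocab: GOVocabulary) -> set[str]:
        """Map the 1-positions back to GO terms."""
        return {vocab.terms[k] for k in np.flatnonzero(self.bits)}


def assemble_homolog_terms(
    accession: str, homologs: HomologMap, annotations: AnnotationMap
) -> set[str]:
    """Pool the GO annotations of all retained homologs of a protein.

    Returns the empty set when the protein has no homologs or none of them
    are annotated.
    """
    terms: set[str] = set()
    for subject in homologs.homologs_of(accession):
        terms |= annotations.terms_of(subject)
    return terms


def build_records(
    accessions: Iterable[str],
    annotations: AnnotationMap,
    homologs: HomologMap,
    homolog_annotations: AnnotationMap | None = None,
) -> list[ProteinRecord]:
    """Assemble ProteinRecords for a set of accessions.

    ``homolog_annotations`` defaults to ``annotations`` when homolog subjects
    are annotated in the same map.
    """
    ham = homolog_annotations if homolog_annotations is not None else annotations
    return [
        ProteinRecord(
            accession=acc,
            target_terms=set(annotations.terms_of(acc)),
            homolog_terms=assemble_homolog_terms(acc, homologs, ham),
        )
        for acc in accessions
    ]


def filter_unannotated(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Drop records with empty target AND homolog term sets; keep input order."""
    return [r for r in records if r.is_annotated]


def build_vocabulary(records: Sequence[ProteinRecord]) -> GOVocabulary:
    """Union of target and homolog term sets over all records, sorted.

    Raises ``ValueError`` when no record contributes any term (a dataset
    with no features cannot be vectorized).
    """
    if not records:
        raise ValueError("cannot build a vocabulary from zero records")
    terms: set[str] = set()
    for rec in records:
        terms |= rec.target_terms
        terms |= rec.homolog_terms
    if not terms:
        raise ValueError("all records are empty on both term sets; no features")
    return GOVocabulary.from_terms(terms)


def build_instance(
    record: ProteinRecord, kind: InstanceKind, vocab: GOVocabulary
) -> InstanceVector:
    """Encode one term set of a record as a binary vector over the vocabulary.

    Terms absent from the vocabulary are silently dropped: the vocabulary is
    fixed at training time and unseen test-time terms contribute no bit.
    """
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    bits = np.zeros(len(vocab), dtype=np.uint8)
    for term in record.terms(kind):
        k = vocab.index.get(term)
        if k is not None:
            bits[k] = 1
    return InstanceVector(accession=record.accession, kind=kind, bits=bits)


class GOInstanceVectorizer(TransformerMixin, BaseEstimator):
    """Vectorize protein records into a binary instance matrix.

    A scikit-learn transformer: ``fit`` learns the GO vocabulary from the
    training records (both term channels), ``transform`` encodes one channel
    selected by ``kind``.

    Parameters
    ----------
    kind : {"target", "homolog"}
        Which term set to encode.

    Attributes
    ----------
    vocabulary_ : GOVocabulary
        Sorted training vocabulary.
    """

    def __init__(self, kind: InstanceKind = "target"):
        self.kind = kind

    def fit(self, X: Sequence[ProteinRecord], y=None) -> "GOInstanceVectorizer":
        self.vocabulary_ = build_vocabulary(list(X))
        return self

    def transform(self, X: Sequence[ProteinRecord]) -> np.ndarray:
        if not hasattr(self, "vocabulary_"):
            raise RuntimeError("GOInstanceVectorizer is not fitted")
        if X is None or len(X) == 0:
            return np.zeros((0, len(self.vocabulary_)), dtype=np.uint8)
        return np.vstack(
            [build_instance(rec, self.kind, self.vocabulary_).bits for rec in X]
        )

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.vocabulary_.terms, dtype=object)
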