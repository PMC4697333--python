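"""The multi-label multi-instance classifier.

One Gaussian-kernel support vector machine is trained over label-combination
codes: every distinct label set observed in training becomes one class of a
multi-class problem, so a single model covers the whole multi-label task.
Each protein contributes up to two independent training examples — its
target instance and its homolog instance — both carrying the protein's
combination code; this augmentation is how homolog knowledge enters the
model. At prediction time the two instances are scored separately and each
decodes to a full label set.

Cross-validation folds are drawn at the protein level so that the target and
homolog instances of one protein always share a fold; splitting at the
instance level would leak a held-out protein's annotations into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import (
    INSTANCE_KINDS,
    GOVocabulary,
    InstanceKind,
    InstanceVector,
    ProteinRecord,
    build_instance,
    build_vocabulary,
    filter_unannotated,
)
from .labels import CombinationCodebook, LabelAssignment, LabelSet, encode_combinations
from .metrics import MetricsReport, compute_report


def gaussian_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """Gaussian (RBF) kernel ``exp(-gamma * ||x - y||^2)``.

    ``gamma`` controls the flexibility of the kernel; the value lies in
    (0, 1] for any pair of equal-length vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    diff = x - y
    return float(np.exp(-gamma * float(diff @ diff)))


@dataclass(frozen=True)
class KernelParams:
    """Gaussian-kernel hyperparameters.

    ``gamma=None`` selects the default 1/|S| where |S| is the vocabulary
    size, so kernel widths track feature dimensionality. ``cost`` is the
    soft-margin regularization constant C.
    """

    gamma: float | None = None
    cost: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.cost <= 0:
            raise ValueError("cost must be positive")

    def resolved_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features


class LabelPowersetClassifier(ClassifierMixin, BaseEstimator):
    """Multi-label classifier via label-combination codes and an RBF SVM.

    ``fit`` accepts a binary feature matrix and one label set per row;
    distinct label sets are encoded as consecutive integer codes and a
    single multi-class ``sklearn.svm.SVC`` is trained on them. ``predict``
    scores each class with one-vs-rest decision values and returns the
    decoded label set of the best code; ties break toward the lowest code.

    Parameters
    ----------
    gamma : float or None, default None
        Gaussian-kernel width; ``None`` means ``1 / n_features``.
    C : float, default 1.0
        Soft-margin cost.

    Attributes
    ----------
    codebook_ : CombinationCodebook
        Bijection between observed label sets and integer codes.
    svc_ : sklearn.svm.SVC
        The fitted kernel machine over codes.
    classes_ : ndarray
        Sorted combination codes seen in training.
    """

    def __init__(self, gamma: float | None = None, C: float = 1.0):
        self.gamma = gamma
        self.C = C

    def fit(self, X: np.ndarray, y: Sequence[LabelSet]) -> "LabelPowersetClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be 2-d with one row per label set")
        labels_of = {str(i): frozenset(s) for i, s in enumerate(y)}
        self.codebook_ = encode_combinations(labels_of)
        if len(self.codebook_) < 2:
            raise ValueError("need at least 2 distinct label combinations to train")
        codes = np.array([self.codebook_.encode(s) for s in y], dtype=int)
        params = KernelParams(gamma=self.gamma, cost=self.C)
        self.gamma_ = params.resolved_gamma(X.shape[1])
        self.svc_ = SVC(
            kernel="rbf",
            gamma=self.gamma_,
            C=self.C,
            decision_function_shape="ovr",
        )
        self.svc_.fit(X, codes)
        self.classes_ = self.svc_.classes_
        return self

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        """Predict one combination code per row, deterministically.

        The argmax of the one-vs-rest decision values is taken; np.argmax
        returns the first maximum, and classes are sorted ascending, so ties
        resolve to the lowest code.
        """
        check_is_fitted(self, "svc_")
        X = np.asarray(X, dtype=float)
        df = self.svc_.decision_function(X)
        if df.ndim == 1:  # binary case: positive margin -> second class
            idx = (df > 0).astype(int)
        else:
            idx = np.argmax(df, axis=1)
        return self.classes_[idx]

    def predict(self, X: np.ndarray) -> list[LabelSet]:
        return [self.codebook_.decode(int(c)) for c in self.predict_codes(X)]


@dataclass
class TrainedModel:
    """A fitted pathway model bundled with its vocabulary and codebook."""

    codebook: CombinationCodebook
    kernel: KernelParams
    vocab: GOVocabulary
    clf: LabelPowersetClassifier


@dataclass
class PredictionResult:
    """Per-instance-kind predicted label sets for one protein."""

    accession: str
    by_kind: dict[InstanceKind, LabelSet] = field(default_factory=dict)


def train(
    instances: Sequence[InstanceVector],
    assignment: LabelAssignment,
    codebook: CombinationCodebook,
    params: KernelParams,
    vocab: GOVocabulary,
) -> TrainedModel:
    """Fit the single multi-class kernel model on instance vectors.

    Every instance is an independent training example carrying its
    protein's combination code, so a protein with both a target and a
    homolog instance appears twice in the design with the same code.
    """
    if not instances:
        raise ValueError("no training instances")
    X = np.vstack([iv.bits for iv in instances]).astype(float)
    y = [frozenset(assignment.labels_of[iv.accession]) for iv in instances]
    clf = LabelPowersetClassifier(gamma=params.gamma, C=params.cost)
    clf.fit(X, y)
    return TrainedModel(codebook=clf.codebook_, kernel=params, vocab=vocab, clf=clf)


def build_training_instances(
    records: Sequence[ProteinRecord], vocab: GOVocabulary
) -> list[InstanceVector]:
    """Both instance kinds of every record with a non-empty term set."""
    out: list[InstanceVector] = []
    for rec in records:
        for kind in INSTANCE_KINDS:
            if rec.terms(kind):
                out.append(build_instance(rec, kind, vocab))
    return out


def predict(model: TrainedModel, record: ProteinRecord) -> PredictionResult:
    """Predict label sets for each non-empty instance kind of a protein."""
    if not record.is_annotated:
        raise ValueError(f"{record.accession!r} has no target or homolog terms (removal rule)")
    result = PredictionResult(accession=record.accession)
    for kind in INSTANCE_KINDS:
        if not record.terms(kind):
            continue
        bits = build_instance(record, kind, model.vocab).bits[None, :]
        result.by_kind[kind] = model.clf.predict(bits)[0]
    return result


def predict_many(model: TrainedModel, records: Sequence[ProteinRecord]) -> list[PredictionResult]:
    """Vectorized prediction over many records (one SVC call per kind)."""
    results = {r.accession: PredictionResult(accession=r.accession) for r in records}
    for kind in INSTANCE_KINDS:
        subset = [r for r in records if r.terms(kind)]
        if not subset:
            continue
        X = np.vstack([build_instance(r, kind, model.vocab).bits for r in subset]).astype(float)
        for rec, labels in zip(subset, model.clf.predict(X)):
            results[rec.accession].by_kind[kind] = labels
    return [results[r.accession] for r in records]


class MultiInstancePathwayModel(BaseEstimator):
    """High-level estimator: protein records in, per-kind label sets out.

    ``fit(records, assignment)`` applies the removal rule, learns the GO
    vocabulary from the training records, builds both instance kinds as
    independent examples and trains the label-powerset SVM.
    ``predict(records)`` returns one :class:`PredictionResult` per record.
    """

    def __init__(self, gamma: float | None = None, C: float = 1.0):
        self.gamma = gamma
        self.C = C

    def fit(
        self, records: Sequence[ProteinRecord], assignment: LabelAssignment
    ) -> "MultiInstancePathwayModel":
        kept = filter_unannotated(records)
        missing = [r.accession for r in kept if r.accession not in assignment.labels_of]
        if missing:
            raise ValueError(f"records without labels: {missing[:5]}")
        vocab = build_vocabulary(kept)
        instances = build_training_instances(kept, vocab)
        params = KernelParams(gamma=self.gamma, cost=self.C)
        codebook = encode_combinations(
            {r.accession: assignment.labels_of[r.accession] for r in kept}
        )
        self.model_ = train(instances, assignment, codebook, params, vocab)
        return self

    def predict(self, records: Sequence[ProteinRecord]) -> list[PredictionResult]:
        check_is_fitted(self, "model_")
        kept = filter_unannotated(records)
        return predict_many(self.model_, kept)


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded uniform shuffle followed by a contiguous split into k folds."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} proteins into {k} non-empty folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.asarray(part) for part in np.array_split(order, k)]


def cross_validate(
    records: Sequence[ProteinRecord],
    assignment: LabelAssignment,
    k: int = 10,
    seed: int = 0,
    params: KernelParams | None = None,
) -> dict[InstanceKind, MetricsReport]:
    """Protein-level k-fold cross-validation, metrics per instance kind.

    Proteins are partitioned into k folds (both instances of a protein stay
    together). Per fold the vocabulary, codebook and model are rebuilt from
    the training folds only; out-of-fold predictions are pooled over all
    folds and the multi-label metrics are computed once per instance kind
    over all classes including the negative class.
    """
    params = params or KernelParams()
    kept = filter_unannotated(records)
    folds = make_folds(len(kept), k, seed)
    pooled: dict[InstanceKind, tuple[list[LabelSet], list[LabelSet]]] = {
        kind: ([], []) for kind in INSTANCE_KINDS
    }
    for test_idx in folds:
        if len(test_idx) == 0:
            raise ValueError("empty test fold")
        test_mask = np.zeros(len(kept), dtype=bool)
        test_mask[test_idx] = True
        train_records = [r for i, r in enumerate(kept) if not test_mask[i]]
        test_records = [kept[i] for i in test_idx]
        vocab = build_vocabulary(train_records)
        instances = build_training_instances(train_records, vocab)
        codebook = encode_combinations(
            {r.accession: assignment.labels_of[r.accession] for r in train_records}
        )
        model = train(instances, assignment, codebook, params, vocab)
        for rec, result in zip(test_records, predict_many(model, test_records)):
            truth = assignment.labels_of[rec.accession]
            for kind, predicted in result.by_kind.items():
                pooled[kind][0].append(truth)
                pooled[kind][1].append(predicted)
    n_classes = assignment.n_classes
    return {
        kind: compute_report(true_sets, pred_sets, n_classes)
        for kind, (true_sets, pred_sets) in pooled.items()
        if true_sets
    }
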