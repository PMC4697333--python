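import numpy as np
import pytest

from sigpath.classifier import (
    KernelParams,
    LabelPowersetClassifier,
    MultiInstancePathwayModel,
    build_training_instances,
    cross_validate,
    gaussian_kernel,
    make_folds,
    predict,
    train,
)
from sigpath.features import ProteinRecord, build_vocabulary, filter_unannotated
from sigpath.labels import LabelAssignment, encode_combinations

G = [f"GO:{i:07d}" for i in range(1, 21)]


def _separable_dataset():
    """Three classes with disjoint one-term signatures; both instance kinds."""
    records, labels = [], {}
    for cls, term in enumerate([G[0], G[1], G[2]], start=1):
        for i in range(6):
            acc = f"C{cls}_{i}"
            records.append(
                ProteinRecord(accession=acc, target_terms={term}, homolog_terms={term, G[10 + cls]})
            )
            labels[acc] = frozenset({cls})
    return records, LabelAssignment(labels_of=labels, d=3)


class TestGaussianKernel:
    def test_self_similarity_is_one(self, rng):
        for _ in range(10):
            x = rng.integers(0, 2, size=30)
            assert gaussian_kernel(x, x, gamma=0.7) == 1.0

    def test_hamming_distance_closed_form(self):
        x = np.array([1, 0, 1, 0])
        y = np.array([0, 0, 1, 1])  # Hamming distance 2
        assert gaussian_kernel(x, y, gamma=0.5) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(20):
            x = rng.integers(0, 2, size=15)
            y = rng.integers(0, 2, size=15)
            k = gaussian_kernel(x, y, gamma=0.3)
            assert k == gaussian_kernel(y, x, gamma=0.3)
            assert 0.0 < k <= 1.0

    def test_small_gamma_limit(self, rng):
        x, y = rng.integers(0, 2, size=10), rng.integers(0, 2, size=10)
        assert gaussian_kernel(x, y, gamma=1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_and_bad_gamma(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.ones(3), np.ones(4), gamma=1.0)
        with pytest.raises(ValueError):
            gaussian_kernel(np.ones(3), np.ones(3), gamma=0.0)


class TestKernelParams:
    def test_default_gamma_tracks_vocabulary_size(self):
        assert KernelParams().resolved_gamma(250) == pytest.approx(1 / 250)
        assert KernelParams(gamma=2.0).resolved_gamma(250) == 2.0

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(gamma=-1.0)
        with pytest.raises(ValueError):
            KernelParams(cost=0.0)


class TestTraining:
    def test_memorizes_separable_data(self):
        records, assignment = _separable_dataset()
        vocab = build_vocabulary(records)
        instances = build_training_instances(records, vocab)
        codebook = encode_combinations(assignment.labels_of)
        model = train(instances, assignment, codebook, KernelParams(), vocab)
        for rec in records:
            result = predict(model, rec)
            assert result.by_kind["target"] == assignment.labels_of[rec.accession]
            assert result.by_kind["homolog"] == assignment.labels_of[rec.accession]

    def test_both_instances_enter_design(self):
        records, _ = _separable_dataset()
        vocab = build_vocabulary(records)
        instances = build_training_instances(records, vocab)
        assert len(instances) == 2 * len(records)
        kinds = {iv.accession: set() for iv in instances}
        for iv in instances:
            kinds[iv.accession].add(iv.kind)
        assert all(v == {"target", "homolog"} for v in kinds.values())

    def test_homolog_only_record_predicts_homolog_kind_only(self):
        records, assignment = _separable_dataset()
        vocab = build_vocabulary(records)
        model = train(
            build_training_instances(records, vocab),
            assignment,
            encode_combinations(assignment.labels_of),
            KernelParams(),
            vocab,
        )
        orphan = ProteinRecord(accession="Q", target_terms=set(), homolog_terms={G[0]})
        result = predict(model, orphan)
        assert set(result.by_kind) == {"homolog"}

    def test_empty_record_rejected(self):
        records, assignment = _separable_dataset()
        vocab = build_vocabulary(records)
        model = train(
            build_training_instances(records, vocab),
            assignment,
            encode_combinations(assignment.labels_of),
            KernelParams(),
            vocab,
        )
        with pytest.raises(ValueError, match="removal rule"):
            predict(model, ProteinRecord(accession="Q"))

    def test_all_zero_projection_still_predicts(self):
        records, assignment = _separable_dataset()
        vocab = build_vocabulary(records)
        model = train(
            build_training_instances(records, vocab),
            assignment,
            encode_combinations(assignment.labels_of),
            KernelParams(),
            vocab,
        )
        # annotated only with a term unseen in training -> all-zero vector
        stranger = ProteinRecord(accession="Q", target_terms={"GO:9999999"})
        result = predict(model, stranger)
        assert result.by_kind["target"] in set(model.codebook.combo_to_code)

    def test_fewer_than_two_codes_rejected(self):
        X = np.eye(4)
        with pytest.raises(ValueError, match="2 distinct"):
            LabelPowersetClassifier().fit(X, [frozenset({1})] * 4)

    def test_label_relabeling_symmetry(self):
        """Relabeling classes by a bijection permutes predictions identically."""
        records, assignment = _separable_dataset()
        perm = {1: 3, 2: 1, 3: 2}
        relabeled = LabelAssignment(
            labels_of={
                acc: frozenset({perm[j] for j in s}) for acc, s in assignment.labels_of.items()
            },
            d=3,
        )
        vocab = build_vocabulary(records)
        instances = build_training_instances(records, vocab)
        m1 = train(instances, assignment, encode_combinations(assignment.labels_of), KernelParams(), vocab)
        m2 = train(instances, relabeled, encode_combinations(relabeled.labels_of), KernelParams(), vocab)
        for rec in records:
            p1 = predict(m1, rec).by_kind["target"]
            p2 = predict(m2, rec).by_kind["target"]
            assert frozenset({perm[j] for j in p1}) == p2


class TestEstimatorSurface:
    def test_get_set_params_clone(self):
        from sklearn.base import clone

        est = MultiInstancePathwayModel(gamma=0.5, C=2.0)
        assert est.get_params() == {"gamma": 0.5, "C": 2.0}
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_predict_roundtrip(self):
        records, assignment = _separable_dataset()
        est = MultiInstancePathwayModel().fit(records, assignment)
        results = est.predict(records)
        assert all(
            r.by_kind["target"] == assignment.labels_of[r.accession] for r in results
        )

    def test_unlabeled_record_rejected_at_fit(self):
        records, assignment = _separable_dataset()
        records = records + [ProteinRecord("UNKNOWN", target_terms={G[0]})]
        with pytest.raises(ValueError, match="without labels"):
            MultiInstancePathwayModel().fit(records, assignment)


class TestFolds:
    def test_true_partition(self):
        folds = make_folds(47, 10, seed=3)
        flat = np.concatenate(folds)
        assert sorted(flat.tolist()) == list(range(47))
        assert all(len(f) > 0 for f in folds)

    def test_seed_determinism(self):
        a = make_folds(30, 5, seed=8)
        b = make_folds(30, 5, seed=8)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_proteins(self):
        with pytest.raises(ValueError):
            make_folds(3, 10, seed=0)


class TestCrossValidation:
    def test_determinism_and_bounds(self, small_corpus_training):
        records, assignment = small_corpus_training
        r1 = cross_validate(records, assignment, k=5, seed=4)
        r2 = cross_validate(records, assignment, k=5, seed=4)
        for kind in r1:
            assert r1[kind].exact_match_ratio == r2[kind].exact_match_ratio
            assert r1[kind].macro_f == r2[kind].macro_f
            assert 0.0 <= r1[kind].exact_match_ratio <= 1.0
            assert 0.0 <= r1[kind].micro_f <= 1.0

    def test_fold_sizes_cover_all_proteins(self, small_corpus_training):
        records, assignment = small_corpus_training
        reports = cross_validate(records, assignment, k=5, seed=4)
        # every protein has a target instance in this corpus
        assert reports["target"].l == len(filter_unannotated(records))

    def test_recovery_on_separable_corpus(self, small_corpus_training):
        """Planted labels are recovered out-of-fold on strongly separable data."""
        records, assignment = small_corpus_training
        reports = cross_validate(records, assignment, k=5, seed=4)
        assert reports["target"].exact_match_ratio >= 0.85
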