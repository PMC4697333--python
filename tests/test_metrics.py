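"""Metric unit tests, with an independent brute-force oracle.

The oracle implements the exact-match ratio and F-measure definitions by
naive per-cell loops, independently of the vectorized implementation.
"""

import numpy as np
import pytest

from sigpath.metrics import (
    binarize,
    compute_report,
    exact_match_ratio,
    label_f_measure,
    macro_average_f,
    micro_average_f,
)

# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def oracle_exact_match(Y, Yhat):
    hits = 0
    for i in range(len(Y)):
        hits += all(Y[i][j] == Yhat[i][j] for j in range(len(Y[i])))
    return hits / len(Y)


def oracle_label_f(Y, Yhat, j):
    tp = sum(Y[i][j - 1] * Yhat[i][j - 1] for i in range(len(Y)))
    denom = sum(Yhat[i][j - 1] for i in range(len(Y))) + sum(Y[i][j - 1] for i in range(len(Y)))
    return None if denom == 0 else 2 * tp / denom

def oracle_macro(Y, Yhat):
    fs = [f for j in range(1, len(Y[0]) + 1) if (f := oracle_label_f(Y, Yhat, j)) is not None]
    return sum(fs) / len(fs)


def oracle_micro(Y, Yhat):
    tp = sum(Y[i][j] * Yhat[i][j] for i in range(len(Y)) for j in range(len(Y[0])))
    denom = sum(Y[i][j] + Yhat[i][j] for i in range(len(Y)) for j in range(len(Y[0])))
    return 2 * tp / denom


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


class TestBinarize:
    def test_worked_row(self):
        assert binarize([{1, 2, 4}], d=4).tolist() == [[1, 1, 0, 1]]

    def test_empty_set_row(self):
        assert binarize([set()], d=3).tolist() == [[0, 0, 0]]

    def test_round_trip(self):
        sets = [{1, 3}, {2}, set()]
        Y = binarize(sets, d=3)
        back = [{j + 1 for j in np.flatnonzero(row)} for row in Y]
        assert back == sets

    def test_out_of_range_label(self):
        with pytest.raises(ValueError):
            binarize([{5}], d=4)


class TestWorkedExample:
    """True {1,2,4} vs predicted {1,2} with d=4, l=1."""

    Y = binarize([{1, 2, 4}], 4)
    Yhat = binarize([{1, 2}], 4)

    def test_exact_match_is_miss(self):
        assert exact_match_ratio(self.Y, self.Yhat) == 0.0

    def test_per_label_f(self):
        assert label_f_measure(self.Y, self.Yhat, 1) == 1.0
        assert label_f_measure(self.Y, self.Yhat, 2) == 1.0
        assert label_f_measure(self.Y, self.Yhat, 3) is None  # 0/0 case
        assert label_f_measure(self.Y, self.Yhat, 4) == 0.0

    def test_macro_excludes_undefined(self):
        assert macro_average_f(self.Y, self.Yhat) == pytest.approx(2 / 3)

    def test_micro(self):
        assert micro_average_f(self.Y, self.Yhat) == pytest.approx(0.8)


class TestEdgeCases:
    def test_perfect_prediction_all_ones(self):
        Y = binarize([{1}, {2, 3}], 3)
        r = compute_report([{1}, {2, 3}], [{1}, {2, 3}], 3)
        assert r.exact_match_ratio == r.macro_f == r.micro_f == 1.0
        assert exact_match_ratio(Y, Y) == 1.0

    def test_partial_exact_match(self):
        sets_true = [{1}, {2}, {1, 2}, {2}]
        sets_pred = [{1}, {2}, {1, 2}, {1}]
        Y, Yhat = binarize(sets_true, 2), binarize(sets_pred, 2)
        assert exact_match_ratio(Y, Yhat) == 0.75

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            exact_match_ratio(binarize([{1}], 2), binarize([{1}], 3))

    def test_all_undefined_macro_is_error(self):
        Y = binarize([set()], 3)
        with pytest.raises(ValueError):
            macro_average_f(Y, Y)
        with pytest.raises(ValueError):
            micro_average_f(Y, Y)

    def test_row_permutation_invariance(self, rng):
        true = [{1}, {2}, {1, 3}, {3}, {2, 3}]
        pred = [{1}, {3}, {1}, {3}, {2}]
        Y, Yhat = binarize(true, 3), binarize(pred, 3)
        perm = rng.permutation(5)
        assert exact_match_ratio(Y[perm], Yhat[perm]) == exact_match_ratio(Y, Yhat)
        assert micro_average_f(Y[perm], Yhat[perm]) == micro_average_f(Y, Yhat)
        assert macro_average_f(Y[perm], Yhat[perm]) == macro_average_f(Y, Yhat)


class TestOracleEquivalence:
    def test_200_random_matrices(self):
        """Vectorized metrics agree with the naive loop implementation to
        1e-12 on 200 seeded random (Y, Yhat) pairs."""
        rng = np.random.default_rng(42)
        checked_macro = 0
        for _ in range(200):
            l = int(rng.integers(1, 21))
            d = int(rng.integers(1, 7))
            Y = (rng.random((l, d)) < 0.35).astype(int)
            Yhat = (rng.random((l, d)) < 0.35).astype(int)
            Yl, Yhl = Y.tolist(), Yhat.tolist()
            assert exact_match_ratio(Y, Yhat) == pytest.approx(oracle_exact_match(Yl, Yhl), abs=1e-12)
            for j in range(1, d + 1):
                got = label_f_measure(Y, Yhat, j)
                want = oracle_label_f(Yl, Yhl, j)
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want, abs=1e-12)
            if any(oracle_label_f(Yl, Yhl, j) is not None for j in range(1, d + 1)):
                assert macro_average_f(Y, Yhat) == pytest.approx(oracle_macro(Yl, Yhl), abs=1e-12)
                assert micro_average_f(Y, Yhat) == pytest.approx(oracle_micro(Yl, Yhl), abs=1e-12)
                checked_macro += 1
        assert checked_macro > 150  # the oracle actually exercised the averages


def test_single_label_reduction_to_accuracy(rng):
    """With exactly one label per instance, exact match ratio equals
    plain multi-class accuracy."""
    true = [int(x) for x in rng.integers(1, 5, size=100)]
    pred = [int(x) for x in rng.integers(1, 5, size=100)]
    accuracy = np.mean([t == p for t, p in zip(true, pred)])
    Y = binarize([{t} for t in true], 4)
    Yhat = binarize([{p} for p in pred], 4)
    assert exact_match_ratio(Y, Yhat) == pytest.approx(float(accuracy))
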