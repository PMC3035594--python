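"""Top-scoring-pair scores, classification rule, and LOOCV."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ildnet import ExpressionMatrix, tsp_classify, tsp_cv, tsp_scores


def _mat(arr, features=None):
    arr = np.asarray(arr, dtype=float)
    idx = features or [f"f{i:02d}" for i in range(arr.shape[0])]
    return ExpressionMatrix(pd.DataFrame(
        arr, index=idx, columns=[f"s{j:02d}" for j in range(arr.shape[1])]))


def brute_force_scores(X, ids, labels, c1, c2):
    """O(p^2 n) reference: per-pair strict-event probabilities by loop."""
    lab = np.asarray(labels)
    out = {}
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = (i, j) if ids[i] < ids[j] else (j, i)
        p1 = np.mean([X[a, s] < X[b, s] for s in range(X.shape[1]) if lab[s] == c1])
        p2 = np.mean([X[a, s] < X[b, s] for s in range(X.shape[1]) if lab[s] == c2])
        out[(ids[a], ids[b])] = abs(p1 - p2)
    return out


def test_perfect_reciprocal_pair_scores_one_and_ranks_first():
    rng = np.random.default_rng(0)
    n1, n2 = 4, 4
    X = rng.standard_normal((6, n1 + n2))
    X[0] = [5, 6, 7, 5.5, 1, 2, 3, 1.5]   # high in class1, low in class2
    X[1] = [1, 2, 3, 1.5, 5, 6, 7, 5.5]   # reciprocal
    m = _mat(X)
    labels = ["ild"] * n1 + ["normal"] * n2
    scores = tsp_scores(m, labels)
    best = scores[0]
    assert {best.feature_i, best.feature_j} == {"f00", "f01"}
    assert best.delta == 1.0


def test_self_copy_pair_scores_zero():
    X = np.vstack([np.arange(6), np.arange(6)])
    scores = tsp_scores(_mat(X), ["a"] * 3 + ["b"] * 3)
    assert scores[0].delta == 0.0  # strict event always false on ties


def test_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    X = np.round(rng.standard_normal((8, 10)), 1)  # rounding creates ties
    m = _mat(X)
    labels = ["a"] * 5 + ["b"] * 5
    scores = tsp_scores(m, labels)
    oracle = brute_force_scores(X, m.feature_ids, labels, "a", "b")
    assert len(scores) == len(oracle)
    for s in scores:
        assert s.delta == pytest.approx(oracle[(s.feature_i, s.feature_j)])


def test_delta_invariant_under_monotone_transforms():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((10, 8))
    labels = ["a"] * 4 + ["b"] * 4
    base = tsp_scores(_mat(X), labels)
    # different strictly increasing transform per sample
    Y = X.copy()
    for j in range(8):
        Y[:, j] = np.exp(X[:, j]) * (j + 1) + j
    transformed = tsp_scores(_mat(Y), labels)
    for s, t in zip(base, transformed):
        assert (s.feature_i, s.feature_j) == (t.feature_i, t.feature_j)
        assert s.delta == pytest.approx(t.delta)
        assert s.gamma == pytest.approx(t.gamma)


def test_class_relabeling_preserves_delta():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((6, 8))
    d1 = {(s.feature_i, s.feature_j): s.delta for s in tsp_scores(_mat(X), ["a"] * 4 + ["b"] * 4)}
    d2 = {(s.feature_i, s.feature_j): s.delta for s in tsp_scores(_mat(X), ["b"] * 4 + ["a"] * 4)}
    assert d1 == d2


def test_more_than_two_classes_rejected():
    with pytest.raises(ValueError):
        tsp_scores(_mat(np.ones((3, 3))), ["a", "b", "c"])


class TestClassify:
    def _pair(self, p1, p2):
        from ildnet.tsp import PairScore
        return PairScore("fi", "fj", abs(p1 - p2), 0.0, p1, p2, "c1", "c2")

    def test_event_true_votes_high_prevalence_class(self):
        pair = self._pair(0.9, 0.1)
        assert tsp_classify(pair, {"fi": 0.0, "fj": 1.0}) == "c1"
        assert tsp_classify(pair, {"fi": 1.0, "fj": 0.0}) == "c2"

    def test_equal_values_use_false_event_prevalence(self):
        # tie counts as event-false; class2 has higher false-event prevalence
        pair = self._pair(0.9, 0.1)
        assert tsp_classify(pair, {"fi": 1.0, "fj": 1.0}) == "c2"

    def test_prevalence_tie_breaks_lexicographically(self):
        pair = self._pair(0.5, 0.5)
        assert tsp_classify(pair, {"fi": 0.0, "fj": 1.0}) == "c1"

    def test_missing_feature_rejected(self):
        with pytest.raises(KeyError):
            tsp_classify(self._pair(1, 0), {"fi": 0.0})


class TestLOOCV:
    def _planted(self, n_per_class=10, seed=4):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_class
        X = rng.standard_normal((10, n))
        X[0, :n_per_class] += 4
        X[1, n_per_class:] += 4
        return _mat(X), ["a"] * n_per_class + ["b"] * n_per_class

    def test_perfect_pair_gives_perfect_loocv(self):
        m, labels = self._planted()
        assert tsp_cv(m, labels)["accuracy"] == 1.0

    def test_deterministic(self):
        m, labels = self._planted()
        assert tsp_cv(m, labels) == tsp_cv(m, labels)

    def test_training_accuracy_one_for_delta_one_pair(self):
        m, labels = self._planted()
        best = tsp_scores(m, labels)[0]
        assert best.delta == 1.0
        preds = [tsp_classify(best, m.values.iloc[:, k]) for k in range(m.n_samples)]
        assert preds == list(labels)

    def test_permuted_labels_near_majority_rate(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((8, 12))
        m = _mat(X)
        base = np.array(["a"] * 8 + ["b"] * 4)
        accs = []
        for _ in range(20):
            labels = rng.permutation(base)
            if min((labels == "a").sum(), (labels == "b").sum()) < 2:
                continue
            accs.append(tsp_cv(m, labels)["accuracy"])
        # chance-level: near the majority-class rate (8/12), not near 1
        assert 0.3 < np.mean(accs) < 0.9
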