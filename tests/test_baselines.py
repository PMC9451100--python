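import numpy as np
import pytest

from toxmlpath.baselines import (
    binary_relevance_train,
    classifier_chain_train,
    knn_per_label_train,
    make_base_learner,
)
from toxmlpath.datamodel import ValidationError


class StubLearner:
    """Deterministic learner: thresholds the mean of its input columns.

    Records the training feature width so chain-input contracts can be
    asserted, and predicts 1 iff the last training column it saw correlates
    positively ... kept intentionally simple: score = sigmoid(mean(x)).
    """

    def __init__(self):
        self.width = None
        self.coef = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.width = X.shape[1]
        # least-squares linear probe: enough to be perfect on the fixtures
        A = np.column_stack([X, np.ones(len(X))])
        self.coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        assert X.shape[1] == self.width, "chain input width changed between fit and predict"
        s = np.clip(np.column_stack([X, np.ones(len(X))]) @ self.coef, 0, 1)
        return np.column_stack([1 - s, s])

    @property
    def classes_(self):
        return [0, 1]


class TestBinaryRelevance:
    def test_label_predictions_equal_solo_stub(self, rng):
        X = rng.normal(size=(20, 3))
        Y = rng.integers(0, 2, (20, 2))
        br = binary_relevance_train(X, Y, StubLearner)
        for l in range(2):
            solo = StubLearner().fit(X, Y[:, l])
            np.testing.assert_allclose(
                br.predict_scores(X)[:, l], solo.predict_proba(X)[:, 1], atol=1e-12
            )

    def test_independence_from_other_label_columns(self, rng):
        X = rng.normal(size=(20, 3))
        Y = rng.integers(0, 2, (20, 3))
        Y2 = Y.copy()
        Y2[:, 1] = rng.permutation(Y2[:, 1])
        p1 = binary_relevance_train(X, Y, StubLearner).predict_scores(X)[:, 0]
        p2 = binary_relevance_train(X, Y2, StubLearner).predict_scores(X)[:, 0]
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_single_label_equals_base_learner(self, rng):
        X = rng.normal(size=(15, 3))
        Y = rng.integers(0, 2, (15, 1))
        br = binary_relevance_train(X, Y, StubLearner)
        solo = StubLearner().fit(X, Y[:, 0])
        np.testing.assert_allclose(
            br.predict_scores(X)[:, 0], solo.predict_proba(X)[:, 1], atol=1e-12
        )

    def test_single_class_label_constant_predictor(self, rng):
        X = rng.normal(size=(10, 2))
        Y = np.column_stack([np.ones(10, dtype=int), rng.integers(0, 2, 10)])
        br = binary_relevance_train(X, Y, StubLearner)
        assert (br.predict(X)[:, 0] == 1).all()

    def test_input_not_mutated(self, rng):
        X = rng.normal(size=(10, 2))
        Y = rng.integers(0, 2, (10, 2))
        Xc, Yc = X.copy(), Y.copy()
        binary_relevance_train(X, Y, StubLearner)
        np.testing.assert_array_equal(X, Xc)
        np.testing.assert_array_equal(Y, Yc)


class TestClassifierChain:
    def test_chain_width_grows_by_one_per_position(self, rng):
        X = rng.normal(size=(20, 4))
        Y = rng.integers(0, 2, (20, 3))
        cc = classifier_chain_train(X, Y, None, StubLearner)
        assert [m.width for m in cc.models] == [4, 5, 6]

    def test_label_dependency_exploited_vs_br(self, rng):
        """label2 copies label1; features carry no signal for label2.

        CC feeds its label1 prediction forward and matches label1 accuracy
        on label2; BR stays at the prevalence baseline.
        """
        n = 60
        X = rng.normal(size=(n, 3))
        y1 = (X[:, 0] > 0).astype(int)  # perfectly predictable from features
        Y = np.column_stack([y1, y1])   # label2 == label1
        # features 1..2 are noise; only feature 0 informs label1
        cc = classifier_chain_train(X, Y, [0, 1], StubLearner)
        br = binary_relevance_train(X[:, 1:], Y, StubLearner)  # deny br the signal
        cc_pred = cc.predict(X)
        acc1 = (cc_pred[:, 0] == Y[:, 0]).mean()
        acc2 = (cc_pred[:, 1] == Y[:, 1]).mean()
        assert acc2 == pytest.approx(acc1)
        br_acc2 = (br.predict(X[:, 1:])[:, 1] == Y[:, 1]).mean()
        prevalence_baseline = max(Y[:, 1].mean(), 1 - Y[:, 1].mean())
        assert br_acc2 <= prevalence_baseline + 0.15

    def test_invalid_order_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        Y = rng.integers(0, 2, (10, 2))
        with pytest.raises(ValidationError):
            classifier_chain_train(X, Y, [0, 0], StubLearner)

    def test_single_label_chain_equals_br(self, rng):
        X = rng.normal(size=(15, 3))
        Y = rng.integers(0, 2, (15, 1))
        cc = classifier_chain_train(X, Y, [0], StubLearner)
        br = binary_relevance_train(X, Y, StubLearner)
        np.testing.assert_allclose(cc.predict_scores(X), br.predict_scores(X), atol=1e-12)


class TestKnnPerLabel:
    def test_query_on_training_point_k1_copies_labels(self, rng):
        X = rng.normal(size=(10, 3))
        Y = rng.integers(0, 2, (10, 4))
        model = knn_per_label_train(X, Y, k=1)
        np.testing.assert_array_equal(model.predict(X[:3]), Y[:3])

    def test_unanimous_neighbors_predict_positive(self, rng):
        X = np.vstack([rng.normal(size=(6, 2)) + 10, rng.normal(size=(6, 2)) - 10])
        Y = np.vstack([np.ones((6, 1), dtype=int), np.zeros((6, 1), dtype=int)])
        model = knn_per_label_train(X, Y, k=5)
        assert model.predict(np.array([[10.0, 10.0]]))[0, 0] == 1
        assert model.predict(np.array([[-10.0, -10.0]]))[0, 0] == 0

    def test_matches_brute_force_all_pairs_vote(self, rng):
        X = rng.normal(size=(25, 4))
        Y = rng.integers(0, 2, (25, 3))
        Q = rng.normal(size=(7, 4))
        k = 5
        model = knn_per_label_train(X, Y, k=k)
        got = model.predict(Q)
        for qi in range(len(Q)):
            d = [np.linalg.norm(Q[qi] - X[i]) for i in range(len(X))]
            nn = np.argsort(d, kind="stable")[:k]
            votes = Y[nn].sum(axis=0)
            expected = (votes * 2 >= k).astype(int)  # ties predict positive
            np.testing.assert_array_equal(got[qi], expected)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError):
            knn_per_label_train(rng.normal(size=(4, 2)), np.ones((4, 1), dtype=int), k=5)


class TestBaseLearnerFactories:
    @pytest.mark.parametrize("name", ["lr", "rf", "svm"])
    def test_factory_scores_within_unit_interval(self, rng, name):
        X = rng.normal(size=(30, 3))
        Y = (X[:, :2].sum(axis=1) > 0).astype(int).reshape(-1, 1)
        br = binary_relevance_train(X, Y, make_base_learner(name, seed=0))
        s = br.predict_scores(X)
        assert ((s >= 0) & (s <= 1)).all()

    def test_unknown_name_rejected(self):
        with pytest.raises(ValidationError):
            make_base_learner("mlp")
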