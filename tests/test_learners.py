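import math

import numpy as np
import pytest

from orgfocus.corpus_io import ValidationError
from orgfocus.learners import (
    argmax_label,
    classify_by_sections,
    load_model,
    predict_ensemble,
    predict_naive_bayes,
    register_learner,
    save_model,
    train_adaboost,
    train_bagging,
    train_naive_bayes,
)


TOY_VECTORS = [{"a": 3.0, "b": 1.0}, {"a": 1.0, "b": 3.0}]
TOY_LABELS = ["X", "Y"]


class TestNaiveBayes:
    def test_hand_smoothing_arithmetic(self):
        model = train_naive_bayes(TOY_VECTORS, TOY_LABELS, alpha=1.0)
        # P(a|X) = (3+1)/(4+2) = 4/6; P(a|Y) = (1+1)/(4+2) = 2/6
        assert math.exp(model.count_log_lik["X"]["a"]) == pytest.approx(4 / 6)
        assert math.exp(model.count_log_lik["Y"]["a"]) == pytest.approx(2 / 6)

    def test_posterior_matches_hand_bayes(self):
        model = train_naive_bayes(TOY_VECTORS, TOY_LABELS, alpha=1.0)
        post = predict_naive_bayes(model, {"a": 1.0})
        assert post["X"] == pytest.approx(2 / 3)

    def test_empty_vector_returns_priors(self):
        model = train_naive_bayes(TOY_VECTORS + [{"a": 1.0}], ["X", "Y", "X"])
        post = predict_naive_bayes(model, {})
        assert post["X"] == pytest.approx(2 / 3)
        assert post["Y"] == pytest.approx(1 / 3)

    def test_unseen_features_ignored(self):
        model = train_naive_bayes(TOY_VECTORS, TOY_LABELS)
        assert predict_naive_bayes(model, {"zz": 5.0}) == predict_naive_bayes(model, {})

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            train_naive_bayes(TOY_VECTORS, ["X", "X"])

    def test_count_proportionality_under_duplication(self):
        """Duplicating the training set leaves priors unchanged, and leaves
        conditionals unchanged when the pseudo-count scales with the data
        ((2c+2a)/(2C+2a|V|) = (c+a)/(C+a|V|))."""
        m1 = train_naive_bayes(TOY_VECTORS, TOY_LABELS, alpha=1.0)
        m2 = train_naive_bayes(TOY_VECTORS * 2, TOY_LABELS * 2, alpha=2.0)
        m2_same_alpha = train_naive_bayes(TOY_VECTORS * 2, TOY_LABELS * 2, alpha=1.0)
        assert m1.class_log_priors == m2_same_alpha.class_log_priors
        for c in m1.labels:
            for f in m1.count_log_lik[c]:
                assert m1.count_log_lik[c][f] == pytest.approx(
                    m2.count_log_lik[c][f], abs=1e-12
                )

    def test_posterior_matches_exhaustive_enumeration(self):
        """Brute-force Bayes oracle on a toy problem (3 features, 3 classes)."""
        rng = np.random.default_rng(0)
        features = ["f1", "f2", "f3"]
        classes = ["A", "B", "C"]
        vectors, labels = [], []
        for c in classes:
            for _ in range(4):
                vectors.append(
                    {f: float(rng.integers(0, 4)) for f in features}
                )
                labels.append(c)
        alpha = 1.0
        model = train_naive_bayes(vectors, labels, alpha=alpha)
        # independent oracle: explicit multinomial likelihoods, linear space
        totals = {
            c: {f: sum(v[f] for v, l in zip(vectors, labels) if l == c) for f in features}
            for c in classes
        }
        query = {"f1": 2.0, "f2": 0.0, "f3": 1.0}
        scores = {}
        for c in classes:
            denom = sum(totals[c].values()) + alpha * len(features)
            lik = 1.0
            for f in features:
                p = (totals[c][f] + alpha) / denom
                lik *= p ** query[f]
            scores[c] = (labels.count(c) / len(labels)) * lik
        z = sum(scores.values())
        post = predict_naive_bayes(model, query)
        for c in classes:
            assert post[c] == pytest.approx(scores[c] / z, abs=1e-9)

    def test_categorical_feature_conditional(self):
        vectors = [{"jn": "genetics"}, {"jn": "cell"}, {"jn": "genetics"}]
        labels = ["X", "Y", "X"]
        model = train_naive_bayes(vectors, labels, alpha=1.0)
        # P(genetics|X) = (2+1)/(2+2) = 0.75
        assert math.exp(model.cat_tables["jn"]["X"]["genetics"]) == pytest.approx(0.75)
        post = predict_naive_bayes(model, {"jn": "genetics"})
        assert post["X"] > post["Y"]

    def test_matches_sklearn_multinomial_nb(self):
        """Independent library cross-check on dense random count data."""
        sklearn = pytest.importorskip("sklearn.naive_bayes")
        rng = np.random.default_rng(7)
        X = rng.integers(0, 5, size=(30, 6)).astype(float)
        y = np.array(["A", "B", "C"] * 10)
        names = [f"f{j}" for j in range(6)]
        vectors = [dict(zip(names, row)) for row in X]
        model = train_naive_bayes(vectors, list(y), alpha=1.0)
        clf = sklearn.MultinomialNB(alpha=1.0).fit(X, y)
        probs = clf.predict_proba(X[:5])
        for i in range(5):
            post = predict_naive_bayes(model, vectors[i])
            for j, c in enumerate(clf.classes_):
                assert post[c] == pytest.approx(probs[i][j], abs=1e-9)


def _separable_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    vectors, labels = [], []
    for _ in range(n):
        c = rng.choice(["X", "Y"])
        base = {"u": 5.0, "v": 0.0} if c == "X" else {"u": 0.0, "v": 5.0}
        base["w"] = float(rng.integers(0, 3))
        vectors.append(base)
        labels.append(c)
    return vectors, labels


class TestBagging:
    def test_deterministic_under_seed(self):
        vectors, labels = _separable_data()
        e1 = train_bagging(vectors, labels, n_bags=5, seed=3)
        e2 = train_bagging(vectors, labels, n_bags=5, seed=3)
        assert [m.class_log_priors for m, _ in e1.members] == [
            m.class_log_priors for m, _ in e2.members
        ]
        post1 = predict_ensemble(e1, vectors[0])
        post2 = predict_ensemble(e2, vectors[0])
        assert post1 == post2

    def test_single_bag(self):
        vectors, labels = _separable_data()
        ens = train_bagging(vectors, labels, n_bags=1, seed=0)
        assert len(ens.members) == 1 and ens.members[0][1] == 1.0

    def test_training_accuracy_close_to_single_nb(self):
        vectors, labels = _separable_data(n=60, seed=1)
        nb = train_naive_bayes(vectors, labels)
        ens = train_bagging(vectors, labels, n_bags=25, seed=1)
        acc = lambda predict: np.mean(
            [argmax_label(predict(v)) == l for v, l in zip(vectors, labels)]
        )
        assert acc(lambda v: predict_ensemble(ens, v)) >= acc(
            lambda v: predict_naive_bayes(nb, v)
        ) - 0.02


class TestAdaBoost:
    def test_zero_error_early_stop(self):
        vectors, labels = _separable_data()
        ens = train_adaboost(vectors, labels, rounds=10)
        assert len(ens.members) == 1  # separable: first round is perfect

    def test_first_round_equals_plain_nb(self):
        vectors, labels = _separable_data()
        ens = train_adaboost(vectors, labels, rounds=1)
        nb = train_naive_bayes(vectors, labels)
        assert ens.members[0][0].count_log_lik == nb.count_log_lik

    def test_member_weights_match_oracle_recomputation(self):
        # data NB cannot separate perfectly: overlapping counts
        rng = np.random.default_rng(5)
        vectors, labels = [], []
        for i in range(40):
            c = "X" if i % 2 == 0 else "Y"
            mu = 3 if c == "X" else 2
            vectors.append({"u": float(rng.poisson(mu)), "v": float(rng.poisson(5 - mu))})
            labels.append(c)
        ens = train_adaboost(vectors, labels, rounds=3)
        # oracle: replay the weight recursion using the stored members
        n = len(vectors)
        w = np.full(n, 1.0 / n)
        for model, stored_weight in ens.members:
            preds = [argmax_label(predict_naive_bayes(model, v)) for v in vectors]
            miss = np.array([p != g for p, g in zip(preds, labels)], dtype=float)
            eps = float(w @ miss)
            assert 0 < eps < 0.5
            assert stored_weight == pytest.approx(math.log((1 - eps) / eps))
            beta = eps / (1 - eps)
            w = w * np.where(miss > 0, 1.0, beta)
            w /= w.sum()


class TestPredictEnsemble:
    def test_single_member_passthrough(self):
        vectors, labels = _separable_data()
        ens = train_bagging(vectors, labels, n_bags=1, seed=0)
        post = predict_ensemble(ens, vectors[0])
        assert post == predict_naive_bayes(ens.members[0][0], vectors[0])

    def test_bagging_mean_posterior(self):
        vectors, labels = _separable_data()
        ens = train_bagging(vectors, labels, n_bags=2, seed=2)
        post = predict_ensemble(ens, vectors[0])
        manual = {
            c: np.mean(
                [predict_naive_bayes(m, vectors[0])[c] for m, _ in ens.members]
            )
            for c in ("X", "Y")
        }
        for c in manual:
            assert post[c] == pytest.approx(manual[c])

    def test_adaboost_weighted_vote(self):
        from orgfocus.learners import Ensemble

        m_x = train_naive_bayes([{"u": 5.0}, {"v": 5.0}], ["X", "Y"])
        m_y = train_naive_bayes([{"u": 5.0}, {"v": 5.0}], ["Y", "X"])  # flipped
        # two members voting X (weights 1.0, 1.0), one voting Y (weight 0.5):
        # hand tally gives X with vote share 2.0/2.5 = 0.8
        ens = Ensemble(members=((m_x, 1.0), (m_x, 1.0), (m_y, 0.5)), method="adaboost")
        post = predict_ensemble(ens, {"u": 3.0})
        assert argmax_label(post) == "X"
        assert post["X"] == pytest.approx(0.8)


class TestSectionAggregation:
    def test_single_section_matches_whole_doc(self):
        vectors, labels = _separable_data()
        nb = train_naive_bayes(vectors, labels)
        v = vectors[0]
        assert classify_by_sections(nb, [v]) == argmax_label(
            predict_naive_bayes(nb, v)
        )

    def test_majority_of_confident_sections(self):
        nb = train_naive_bayes([{"u": 5.0}, {"v": 5.0}], ["X", "Y"])
        sections = [{"u": 3.0}, {"u": 3.0}, {"v": 3.0}]  # X, X, Y votes
        assert classify_by_sections(nb, sections) == "X"

    def test_kind_weights_can_flip_decision(self):
        nb = train_naive_bayes([{"u": 5.0}, {"v": 5.0}], ["X", "Y"])
        sections = [{"u": 3.0}, {"v": 3.0}]
        kinds = ["methods", "abstract"]
        weighted = classify_by_sections(
            nb, sections, kinds=kinds, kind_weights={"methods": 0.1, "abstract": 10.0}
        )
        assert weighted == "Y"


class TestRegistry:
    def test_register_and_collision(self):
        train = lambda v, l, s: ("const", sorted(set(l))[0])
        predict = lambda m, v: {m[1]: 1.0}
        register_learner("const_test", train, predict)
        with pytest.raises(ValidationError):
            register_learner("const_test", train, predict)


class TestSerialization:
    def test_nb_round_trip_bit_exact(self, tmp_path):
        vectors = TOY_VECTORS + [{"jn": "genetics"}, {"jn": "cell"}]
        labels = ["X", "Y", "X", "Y"]
        model = train_naive_bayes(vectors, labels)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        for v in vectors:
            assert predict_naive_bayes(loaded, v) == predict_naive_bayes(model, v)

    def test_ensemble_round_trip(self, tmp_path):
        vectors, labels = _separable_data()
        ens = train_adaboost(vectors, labels, rounds=2)
        path = tmp_path / "ens.json"
        save_model(ens, path)
        loaded = load_model(path)
        for v in vectors[:5]:
            assert predict_ensemble(loaded, v) == predict_ensemble(ens, v)
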