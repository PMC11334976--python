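import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from plasmocount import (
    InvalidInputError,
    TrainedClassifier,
    apply_normalizer,
    confusion_matrix,
    sample_labelled_features,
    split_dataset,
    train_classifier,
)
from plasmocount.features import FEATURE_COLUMNS


def _gaussian_table(rng, means, n, sd=0.05):
    """Labelled 3-feature table with one isotropic Gaussian blob per class."""
    frames = []
    for label, mu in means.items():
        x = rng.normal(mu, sd, size=(n, 3))
        frames.append(pd.DataFrame(x, columns=list(FEATURE_COLUMNS)).assign(label=label))
    return pd.concat(frames, ignore_index=True)


class TestSplitDataset:
    def test_stratified_fraction(self):
        rng = np.random.default_rng(0)
        table = _gaussian_table(rng, {"a": [0.2] * 3, "b": [0.8] * 3}, 100)
        train, val = split_dataset(table, 0.7, seed=1)
        assert train["label"].value_counts().to_dict() == {"a": 70, "b": 70}
        assert val["label"].value_counts().to_dict() == {"a": 30, "b": 30}

    def test_deterministic_and_partition(self):
        rng = np.random.default_rng(1)
        table = _gaussian_table(rng, {"a": [0.2] * 3, "b": [0.8] * 3}, 20)
        t1, v1 = split_dataset(table, 0.7, seed=9)
        t2, v2 = split_dataset(table, 0.7, seed=9)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(v1, v2)
        merged = pd.concat([t1, v1]).sort_values(list(FEATURE_COLUMNS)).reset_index(drop=True)
        original = table.sort_values(list(FEATURE_COLUMNS)).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, original)

    def test_thin_class_rejected(self):
        table = pd.DataFrame({"h": [0.1, 0.2, 0.3], "s": 0.5, "v": 0.5, "label": ["a", "a", "b"]})
        with pytest.raises(InvalidInputError):
            split_dataset(table, 0.7, seed=0)


class TestTrainAndPredict:
    @pytest.mark.parametrize("kind", ["svm_rbf", "gaussian_nb"])
    def test_separable_clusters_are_perfectly_classified(self, kind):
        rng = np.random.default_rng(2)
        table = _gaussian_table(rng, {"a": [0.2] * 3, "b": [0.8] * 3}, 80, sd=0.03)
        train, val = split_dataset(table, 0.7, seed=3)
        model = train_classifier(train, kind=kind)
        assert model.predict(val) == val["label"].tolist()

    def test_single_class_rejected(self):
        table = pd.DataFrame({"h": [0.1, 0.2], "s": 0.5, "v": 0.5, "label": ["a", "a"]})
        with pytest.raises(InvalidInputError):
            train_classifier(table)

    def test_nb_boundary_at_midpoint_for_symmetric_classes(self):
        """Equal-prior symmetric Gaussians: the NB posterior tie sits exactly
        at the midpoint, so points either side flip class."""
        lo = pd.DataFrame({"h": [0.35, 0.45] * 20, "s": 0.5, "v": 0.5, "label": "a"})
        hi = pd.DataFrame({"h": [0.55, 0.65] * 20, "s": 0.5, "v": 0.5, "label": "b"})
        model = train_classifier(pd.concat([lo, hi], ignore_index=True), kind="gaussian_nb")
        probe = pd.DataFrame({"h": [0.499, 0.501], "s": 0.5, "v": 0.5})
        assert model.predict(probe) == ["a", "b"]

    def test_nb_validation_error_matches_analytic_bayes_error(self):
        """1-D overlap benchmark: unit-Gaussian classes at means 0 and 2
        (affinely mapped into feature range) have Bayes error Phi(-1)."""
        rng = np.random.default_rng(4)
        n = 5000  # per class -> 10,000 total
        a = pd.DataFrame({"h": rng.normal(0.3, 0.1, n), "s": 0.5, "v": 0.5, "label": "a"})
        b = pd.DataFrame({"h": rng.normal(0.5, 0.1, n), "s": 0.5, "v": 0.5, "label": "b"})
        table = pd.concat([a, b], ignore_index=True)
        train, val = split_dataset(table, 0.7, seed=5)
        model = train_classifier(train, kind="gaussian_nb")
        err = np.mean(np.array(model.predict(val)) != val["label"].to_numpy())
        bayes = norm.cdf(-1.0)  # 0.1587
        assert err == pytest.approx(bayes, abs=0.02)

    def test_row_permutation_permutes_predictions(self):
        rng = np.random.default_rng(6)
        table = _gaussian_table(rng, {"a": [0.2] * 3, "b": [0.8] * 3}, 30)
        model = train_classifier(table)
        probe = table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        direct = model.predict(probe)
        rev = model.predict(probe.iloc[::-1].reset_index(drop=True))
        assert direct == rev[::-1]

    def test_feature_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        model = train_classifier(_gaussian_table(rng, {"a": [0.2] * 3, "b": [0.8] * 3}, 10))
        with pytest.raises(InvalidInputError):
            model.predict(pd.DataFrame({"h": [0.1], "s": [0.2]}))


class TestPortablePersistence:
    @pytest.mark.parametrize("kind", ["svm_rbf", "gaussian_nb"])
    def test_json_round_trip_preserves_predictions(self, tmp_path, kind, control_corpus):
        train, val = split_dataset(control_corpus, 0.7, seed=42)
        model = train_classifier(train, kind=kind)
        path = tmp_path / "model.json"
        model.save(path)
        json.loads(path.read_text())  # valid, pickle-free JSON
        reloaded = TrainedClassifier.load(path)
        assert reloaded.predict(val) == model.predict(val)

    @pytest.mark.parametrize("kind", ["svm_rbf", "gaussian_nb"])
    def test_numpy_predictor_matches_sklearn(self, kind, control_corpus):
        """The portable predictor must agree with the fitted scikit-learn
        estimator it was exported from, prediction for prediction."""
        train, val = split_dataset(control_corpus, 0.7, seed=42)
        model = train_classifier(train, kind=kind)
        x_train = apply_normalizer(train, model.normalizer)[list(FEATURE_COLUMNS)].to_numpy()
        y_train = train["label"].map({c: i for i, c in enumerate(model.class_set)}).to_numpy()
        est = (
            SVC(kernel="rbf", C=1.0, gamma="scale")
            if kind == "svm_rbf"
            else GaussianNB()
        )
        est.fit(x_train, y_train)
        x_val = apply_normalizer(val, model.normalizer)[list(FEATURE_COLUMNS)].to_numpy()
        expected = [model.class_set[i] for i in est.predict(x_val)]
        assert model.predict(val) == expected


class TestConfusionMatrix:
    def test_perfect_predictions_give_identity(self):
        labels = ["blue"] * 5 + ["green"] * 4 + ["yellow"] * 3
        cm = confusion_matrix(labels, labels)
        np.testing.assert_array_equal(cm.c, np.eye(3))
        assert cm.support.tolist() == [5, 4, 3]

    def test_hand_counted_three_class_toy(self):
        true = ["a"] * 10 + ["b"] * 10
        pred = ["a"] * 9 + ["b"] + ["b"] * 10
        cm = confusion_matrix(true, pred, class_set=("a", "b", "c"))
        np.testing.assert_allclose(cm.c, [[0.9, 0.1, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        assert cm.support.tolist() == [10, 10, 0]

    def test_rows_with_support_sum_to_one(self, control_model):
        _, cm = control_model
        sums = cm.c.sum(axis=1)
        np.testing.assert_allclose(sums[cm.support > 0], 1.0, atol=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        true = rng.choice(["blue", "green", "yellow"], 60).tolist()
        pred = rng.choice(["blue", "green", "yellow"], 60).tolist()
        cm1 = confusion_matrix(true, pred)
        perm = rng.permutation(60)
        cm2 = confusion_matrix([true[i] for i in perm], [pred[i] for i in perm])
        np.testing.assert_allclose(cm1.c, cm2.c)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion_matrix(["blue"], ["blue", "green"])


class TestClassifierBenchmarks:
    def test_svm_accuracy_at_least_nb_on_default_benchmark(self):
        """On the three-colour benchmark with matched splits the SVM-RBF
        must not trail the naive Bayes baseline."""
        table = sample_labelled_features(700, seed=1234)
        train, val = split_dataset(table, 0.7, seed=42)
        accs = {}
        for kind in ("svm_rbf", "gaussian_nb"):
            model = train_classifier(train, kind=kind)
            accs[kind] = np.mean(np.array(model.predict(val)) == val["label"].to_numpy())
        assert accs["svm_rbf"] >= accs["gaussian_nb"]
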