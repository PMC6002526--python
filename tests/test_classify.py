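"""Classifier and evaluation tests: native Gaussian NB vs a brute-force
density oracle and scikit-learn, the published two-rule tree truth table,
the depth-2 trainer, cross-validation leakage control and chance levels."""

import numpy as np
import pandas as pd
import pytest

from mousemal.classify import (
    ClassifierSpec,
    Depth2Tree,
    GaussianNB,
    PrintedTree,
    evaluate_holdout,
    kfold_cv,
    make_classifier,
    printed_tree,
)


class _Memorizer:
    """Probe classifier: perfect on rows seen in fit, chance elsewhere."""

    def fit(self, X, y):
        self.memory = {tuple(np.asarray(r, dtype=float)): lab for r, lab in zip(np.asarray(X), y)}
        self.fallback = y[0]
        return self

    def predict(self, X):
        return np.array([self.memory.get(tuple(np.asarray(r, dtype=float)), self.fallback) for r in np.asarray(X)])


def _gaussian_table(rng, n=30, sep=4.0):
    X = np.concatenate([rng.normal(0, 1, n), rng.normal(sep, 1, n)])
    y = np.array(["lo"] * n + ["hi"] * n)
    return pd.DataFrame({"f": X}), y


def test_nb_midpoint_boundary():
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"f": np.concatenate([np.linspace(-1, 1, 20), np.linspace(5, 7, 20)])})
    y = np.array(["a"] * 20 + ["b"] * 20)
    nb = GaussianNB().fit(X, y)
    # equal variances and priors: the decision boundary is the midpoint 3
    assert nb.predict(pd.DataFrame({"f": [2.9]}))[0] == "a"
    assert nb.predict(pd.DataFrame({"f": [3.1]}))[0] == "b"


def test_nb_identical_distributions_follow_prior():
    X = pd.DataFrame({"f": [1.0, 2.0, 1.0, 2.0, 1.0, 2.0]})
    y = np.array(["a", "a", "b", "b", "b", "b"])
    nb = GaussianNB().fit(X, y)
    assert all(nb.predict(pd.DataFrame({"f": [1.5, 1.0, 2.0]})) == "b")


def test_nb_matches_brute_force_density_oracle():
    rng = np.random.default_rng(1)
    n, d = 40, 3
    X = rng.normal(0, 1, (n, d)) + np.repeat([[0], [2]], n // 2, axis=0)
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    nb = GaussianNB().fit(pd.DataFrame(X), y)
    Xt = rng.normal(1, 1.5, (25, d))
    expected = []
    for row in Xt:
        scores = {}
        for c in ("a", "b"):
            sub = X[y == c]
            logp = np.log((y == c).mean())
            for j in range(d):
                mu, var = sub[:, j].mean(), sub[:, j].var()
                var = max(var, 1e-9 * X.var(axis=0).max())
                logp += -0.5 * (np.log(2 * np.pi * var) + (row[j] - mu) ** 2 / var)
            scores[c] = logp
        expected.append(max(scores, key=scores.get))
    np.testing.assert_array_equal(nb.predict(pd.DataFrame(Xt)), expected)


def test_nb_matches_sklearn_predictions():
    from sklearn.naive_bayes import GaussianNB as SkNB

    rng = np.random.default_rng(2)
    X = rng.normal(0, 1, (60, 4)) + np.repeat([[0], [1.5], [3]], 20, axis=0)
    y = np.repeat(["a", "b", "c"], 20)
    ours = GaussianNB().fit(pd.DataFrame(X), y)
    theirs = SkNB().fit(X, y)
    Xt = rng.normal(1.5, 2, (40, 4))
    np.testing.assert_array_equal(ours.predict(pd.DataFrame(Xt)), theirs.predict(Xt))


def test_nb_rejects_degenerate_training():
    with pytest.raises(ValueError):
        GaussianNB().fit(pd.DataFrame({"f": [1.0, 2.0]}), np.array(["a", "a"]))


def test_nb_variance_floor_flag():
    X = pd.DataFrame({"f": [1.0, 1.0, 2.0, 2.0], "g": [0.0, 1.0, 0.0, 1.0]})
    nb = GaussianNB().fit(X, np.array(["a", "a", "b", "b"]))
    assert nb.variance_floored


@pytest.mark.parametrize(
    "symptoms,mdtime,expected",
    [
        (2, 9999.0, "truth_teller"),
        (0, 0.0, "truth_teller"),
        (10, 6000.0, "depressed"),
        (10, 3000.0, "liar"),
        (3.5, 6000.0, "depressed"),  # boundary: not < 3.5 -> rule 2
        (10, 4048.0, "liar"),  # boundary: not > 4048 -> liar
    ],
)
def test_printed_tree_truth_table(symptoms, mdtime, expected):
    assert printed_tree({"2DS-c": symptoms, "MD-time 2DS-d": mdtime}) == expected


def test_printed_tree_missing_feature_rejected():
    with pytest.raises(ValueError, match="2DS-c"):
        printed_tree({"MD-time 2DS-d": 100.0})


def test_depth2_tree_separable_depth1_midpoint():
    X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]})
    y = np.array(["a", "a", "a", "b", "b", "b"])
    tree = Depth2Tree().fit(X, y)
    desc = tree.describe()
    assert desc["feature"] == "f"
    assert desc["threshold"] == pytest.approx(5.0)
    assert desc["left"]["leaf"] == "a" and desc["right"]["leaf"] == "b"
    np.testing.assert_array_equal(tree.predict(pd.DataFrame({"f": [0.0, 10.0]})), ["a", "b"])


def test_depth2_tree_single_class_is_leaf():
    tree = Depth2Tree().fit(pd.DataFrame({"f": [1.0, 2.0]}), np.array(["a", "a"]))
    assert tree.describe() == {"leaf": "a"}


def test_depth2_tree_root_uses_symptom_count_on_cohort(small_features):
    feats = small_features[["DS", "2DS-c", "2DS-d", "VAS", "MD-time 2DS-d", "MD-time VAS"]]
    tree = Depth2Tree().fit(feats, small_features["label"].to_numpy())
    root = tree.describe()["feature"]
    assert root in ("2DS-c", "DS", "VAS")  # an endorsement count separates groups


def test_kfold_fold_sizes_60_10():
    rng = np.random.default_rng(3)
    table = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(60)],
            "label": np.repeat(["truth_teller", "depressed", "liar"], 20),
            "2DS-c": rng.normal(0, 1, 60),
            "MD-time 2DS-d": rng.normal(0, 1, 60),
        }
    )
    spec = ClassifierSpec(kind="printed_tree", feature_subset=("2DS-c", "MD-time 2DS-d"))
    rep = kfold_cv(spec, table, k=10, seed=0)
    assert len(rep.fold_accuracies) == 10
    assert int(rep.confusion.to_numpy().sum()) == 60
    with pytest.raises(ValueError):
        kfold_cv(spec, table.head(5), k=10, seed=0)


def test_cv_no_leakage_with_memorizer(small_features):
    """A memorizing classifier must not see validation rows during training."""
    spec = ClassifierSpec(kind="gaussian_nb", feature_subset=("DS", "VAS"))
    rep = kfold_cv(spec, small_features, k=4, seed=0, model_factory=_Memorizer)
    # memorizer falls back to a constant for unseen rows -> far below perfect
    assert rep.accuracy < 60.0


def test_holdout_memorizer_on_train_copy_is_perfect(small_features):
    test = small_features.copy()
    test["participant_id"] = "copy-" + test["participant_id"]
    spec = ClassifierSpec(kind="gaussian_nb", feature_subset=("DS", "VAS"))
    rep = evaluate_holdout(spec, small_features, test, model_factory=_Memorizer)
    assert rep.accuracy == 100.0


def test_holdout_rejects_empty_and_mismatched(small_features):
    spec = ClassifierSpec(kind="gaussian_nb", feature_subset=("DS", "VAS"))
    with pytest.raises(ValueError, match="empty"):
        evaluate_holdout(spec, small_features, small_features.head(0).copy())
    broken = small_features.drop(columns=["VAS"])
    with pytest.raises(ValueError, match="schema"):
        evaluate_holdout(spec, small_features, broken)
    with pytest.raises(ValueError, match="overlap"):
        evaluate_holdout(spec, small_features, small_features)


def test_two_class_mode_excludes_truth_tellers(small_features):
    spec = ClassifierSpec(kind="gaussian_nb", feature_subset="two_class_cfs", mode="two_class")
    rep = kfold_cv(spec, small_features, k=4, seed=0)
    assert set(rep.confusion.index) == {"depressed", "liar"}
    assert int(rep.confusion.to_numpy().sum()) == 16  # 8 + 8, no truth-tellers


def test_permuted_labels_give_chance_level(small_features):
    """Label permutation destroys class information -> ~33% accuracy."""
    accs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        shuffled = small_features.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        spec = ClassifierSpec(kind="gaussian_nb", feature_subset="three_class_cfs")
        accs.append(kfold_cv(spec, shuffled, k=4, seed=seed).accuracy)
    assert abs(np.mean(accs) - 100.0 / 3.0) < 12.0


def test_all_classifiers_beat_chance_on_calibrated_cohort(small_features):
    for kind in ("gaussian_nb", "printed_tree", "depth2_tree", "smo", "lmt", "random_forest"):
        spec = ClassifierSpec(kind=kind, feature_subset="three_class_cfs")
        rep = kfold_cv(spec, small_features, k=4, seed=1)
        assert rep.accuracy > 55.0, kind


def test_make_classifier_unknown_kind():
    with pytest.raises(ValueError):
        make_classifier("quantum_forest")
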