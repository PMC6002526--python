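"""Classifiers and evaluation: native Gaussian naive Bayes, the published
two-rule decision tree, a depth-2 CART-style trainer, pluggable standard
classifiers, stratified k-fold cross-validation and held-out evaluation.

The two interpretable rules of the published tree: a participant endorsing
fewer than 3.5 concordant complex depressive symptoms (2DS-c) is a
truth-teller; otherwise, taking on average more than 4048 ms to reach the
point of maximum deviation on discordant complex questions (MD-time
2DS-d) marks a genuinely depressed patient, else a liar. Both thresholds
are strict: values exactly at a threshold fall to the "else" branch.

Three-class mode scores truth-tellers, liars and depressed; two-class
mode drops truth-tellers entirely (the forensic question is malingered
vs genuine depression), so its confusion matrices are 2x2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .select import NAMED_SUBSETS, NamedSubset

__all__ = [
    "GaussianNB",
    "PrintedTree",
    "Depth2Tree",
    "make_classifier",
    "PLUGGABLE_KINDS",
    "ClassifierSpec",
    "CvReport",
    "printed_tree",
    "kfold_cv",
    "evaluate_holdout",
    "TWO_CLASS_LABELS",
]

TWO_CLASS_LABELS = ("depressed", "liar")

#: published decision-tree thresholds
TREE_SYMPTOM_THRESHOLD = 3.5  # 2DS-c endorsed symptoms
TREE_MDTIME_THRESHOLD = 4048.0  # ms, MD-time on 2DS-d questions


# ---------------------------------------------------------------------------
# native classifiers
# ---------------------------------------------------------------------------


class GaussianNB:
    """Gaussian naive Bayes: class priors from relative frequencies,
    per-feature class-conditional normal densities; prediction is the
    argmax of log prior + sum of log densities. Zero variances are floored
    at 1e-9 times the largest feature variance (flagged)."""

    def __init__(self):
        self.classes_: np.ndarray | None = None
        self.variance_floored = False

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "GaussianNB":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2 or any(np.sum(y == c) < 2 for c in self.classes_):
            raise ValueError("need >=2 classes with >=2 training rows each")
        eps = 1e-9 * max(float(np.var(X, axis=0).max()), 1e-12)
        self.priors_ = np.array([np.mean(y == c) for c in self.classes_])
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        var = np.stack([X[y == c].var(axis=0) for c in self.classes_])
        self.variance_floored = bool(np.any(var < eps))
        self.vars_ = np.maximum(var, eps)
        return self

    def log_joint(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), len(self.classes_)))
        for i in range(len(self.classes_)):
            m, v = self.means_[i], self.vars_[i]
            out[:, i] = np.log(self.priors_[i]) - 0.5 * np.sum(
                np.log(2.0 * np.pi * v) + (X - m) ** 2 / v, axis=1
            )
        return out

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.log_joint(X), axis=1)]


def printed_tree(features: dict | pd.Series) -> str:
    """Classify one participant with the published two-rule tree."""
    for required in ("2DS-c", "MD-time 2DS-d"):
        if required not in features:
            raise ValueError(f"printed tree requires feature {required!r}")
    if features["2DS-c"] < TREE_SYMPTOM_THRESHOLD:
        return "truth_teller"
    if features["MD-time 2DS-d"] > TREE_MDTIME_THRESHOLD:
        return "depressed"
    return "liar"


class PrintedTree:
    """The published tree wrapped in the fit/predict interface (fit is a
    no-op; the rules are fixed)."""

    feature_names = ("2DS-c", "MD-time 2DS-d")

    def fit(self, X: pd.DataFrame, y=None) -> "PrintedTree":
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not isinstance(X, pd.DataFrame):
            raise ValueError("PrintedTree requires a named-column feature table")
        return np.array([printed_tree(row) for _, row in X.iterrows()])


@dataclass
class _Node:
    feature: str | None = None
    threshold: float = 0.0
    prediction: str | None = None
    left: "._Node | None" = None
    right: "._Node | None" = None


class Depth2Tree:
    """Greedy binary decision tree of maximum depth 2.

    Splits minimize weighted Gini impurity; candidate thresholds are the
    midpoints between consecutive distinct sorted values. Pure nodes stop
    early; leaves predict the majority class (first-seen on ties).
    """

    def __init__(self, max_depth: int = 2):
        self.max_depth = max_depth
        self.root: _Node | None = None

    @staticmethod
    def _gini(y: np.ndarray) -> float:
        _, counts = np.unique(y, return_counts=True)
        p = counts / len(y)
        return 1.0 - float(np.sum(p * p))

    @staticmethod
    def _majority(y: np.ndarray) -> str:
        values, counts = np.unique(y, return_counts=True)
        return values[np.argmax(counts)]

    def _best_split(self, X: pd.DataFrame, y: np.ndarray):
        best = (None, 0.0, np.inf)
        n = len(y)
        for feat in X.columns:
            vals = X[feat].to_numpy(dtype=float)
            uniq = np.unique(vals)
            for lo, hi in zip(uniq[:-1], uniq[1:]):
                thr = (lo + hi) / 2.0
                mask = vals <= thr
                score = (
                    mask.sum() * self._gini(y[mask]) + (~mask).sum() * self._gini(y[~mask])
                ) / n
                if score < best[2] - 1e-12:
                    best = (feat, thr, score)
        return best

    def _grow(self, X: pd.DataFrame, y: np.ndarray, depth: int) -> _Node:
        if depth >= self.max_depth or len(np.unique(y)) == 1:
            return _Node(prediction=self._majority(y))
        feat, thr, score = self._best_split(X, y)
        if feat is None or score >= self._gini(y) - 1e-12:
            return _Node(prediction=self._majority(y))
        mask = X[feat].to_numpy(dtype=float) <= thr
        node = _Node(feature=feat, threshold=thr)
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def fit(self, X: pd.DataFrame, y) -> "Depth2Tree":
        self.root = self._grow(X, np.asarray(y), 0)
        return self

    def _predict_one(self, row) -> str:
        node = self.root
        while node.prediction is None:
            node = node.left if row[node.feature] <= node.threshold else node.right
        return node.prediction

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.array([self._predict_one(row) for _, row in X.iterrows()])

    def describe(self) -> dict:
        """Chosen features/thresholds, for comparison with the published tree."""

        def rec(node):
            if node is None:
                return None
            if node.prediction is not None:
                return {"leaf": node.prediction}
            return {
                "feature": node.feature,
                "threshold": node.threshold,
                "left": rec(node.left),
                "right": rec(node.right),
            }

        return rec(self.root)


# ---------------------------------------------------------------------------
# pluggable standard classifiers
# ---------------------------------------------------------------------------

PLUGGABLE_KINDS = ("smo", "lmt", "random_forest")


class _SkAdapter:
    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        self.est.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict(self, X):
        return self.est.predict(np.asarray(X, dtype=float))


def make_classifier(kind: str, seed: int = 0):
    """Instantiate a classifier by kind.

    ``gaussian_nb``, ``printed_tree`` and ``depth2_tree`` are native;
    ``smo`` (linear SVM trained by sequential minimal optimization),
    ``lmt`` (logistic-model stand-in) and ``random_forest`` adapt standard
    scikit-learn implementations.
    """
    if kind == "gaussian_nb":
        return GaussianNB()
    if kind == "printed_tree":
        return PrintedTree()
    if kind == "depth2_tree":
        return Depth2Tree()
    if kind == "smo":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        return _SkAdapter(make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0, random_state=seed)))
    if kind == "lmt":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        return _SkAdapter(
            make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed))
        )
    if kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return _SkAdapter(RandomForestClassifier(n_estimators=100, random_state=seed))
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "gaussian_nb"
    feature_subset: tuple[str, ...] | str = "three_class_cfs"
    mode: str = "three_class"  # or "two_class"

    def features(self) -> tuple[str, ...]:
        if isinstance(self.feature_subset, str):
            return NAMED_SUBSETS[self.feature_subset].features
        return tuple(self.feature_subset)


@dataclass
class CvReport:
    fold_accuracies: list[float]
    accuracy: float  # percent
    confusion: pd.DataFrame
    seed: int | None
    k: int | None
    classifier: str = ""
    mode: str = "three_class"

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "mode": self.mode,
            "k": self.k,
            "seed": self.seed,
            "accuracy_percent": self.accuracy,
            "fold_accuracies": self.fold_accuracies,
            "confusion": {
                str(r): {str(c): int(v) for c, v in row.items()}
                for r, row in self.confusion.to_dict(orient="index").items()
            },
        }


def _apply_mode(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    if mode == "two_class":
        return table[table["label"].isin(TWO_CLASS_LABELS)].reset_index(drop=True)
    if mode != "three_class":
        raise ValueError(f"unknown mode {mode!r}")
    return table


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, labels: list[str]) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y_true, y_pred):
        if p not in mat.columns:  # e.g. printed tree predicting truth_teller in two-class mode
            mat[p] = 0
        mat.loc[t, p] += 1
    return mat


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def _plain_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [np.array(sorted(f)) for f in np.array_split(idx, k)]


def kfold_cv(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    model_factory=None,
) -> CvReport:
    """k-fold cross-validation; each fold serves once as validation.

    Folds are stratified by class by default (switchable). Deterministic
    for a fixed seed. ``model_factory`` overrides the classifier
    construction (used for probes in tests).
    """
    data = _apply_mode(table, spec.mode)
    n = len(data)
    if k > n:
        raise ValueError(f"k={k} exceeds cohort size {n}")
    labels = data["label"].to_numpy()
    feats = data.loc[:, list(spec.features())]
    rng = np.random.default_rng(seed)
    folds = (
        _stratified_folds(labels, k, rng) if stratified else _plain_folds(n, k, rng)
    )
    class_order = sorted(np.unique(labels))
    fold_acc = []
    conf = pd.DataFrame(0, index=class_order, columns=class_order, dtype=int)
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        model = model_factory() if model_factory else make_classifier(spec.kind, seed)
        model.fit(feats.iloc[train], labels[train])
        pred = np.asarray(model.predict(feats.iloc[f]))
        fold_acc.append(float(np.mean(pred == labels[f])))
        conf = conf.add(_confusion(labels[f], pred, class_order), fill_value=0).astype(int)
    total = int(conf.to_numpy().sum())
    correct = int(np.trace(conf.loc[class_order, class_order].to_numpy()))
    return CvReport(
        fold_accuracies=fold_acc,
        accuracy=100.0 * correct / total,
        confusion=conf,
        seed=seed,
        k=k,
        classifier=spec.kind,
        mode=spec.mode,
    )


def evaluate_holdout(
    spec: ClassifierSpec,
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    seed: int = 0,
    model_factory=None,
) -> CvReport:
    """Fit on the training cohort, score on a disjoint held-out cohort."""
    missing = set(spec.features()) - set(test_table.columns)
    if missing or set(spec.features()) - set(train_table.columns):
        raise ValueError("train/test feature schema mismatch")
    train = _apply_mode(train_table, spec.mode)
    test = _apply_mode(test_table, spec.mode)
    if len(test) == 0:
        raise ValueError("empty test cohort")
    overlap = set(train["participant_id"]) & set(test["participant_id"])
    if overlap:
        raise ValueError(f"train and test cohorts overlap: {sorted(overlap)[:3]}")
    model = model_factory() if model_factory else make_classifier(spec.kind, seed)
    model.fit(train.loc[:, list(spec.features())], train["label"].to_numpy())
    pred = np.asarray(model.predict(test.loc[:, list(spec.features())]))
    y = test["label"].to_numpy()
    class_order = sorted(np.unique(np.concatenate([y, train["label"].to_numpy()])))
    conf = _confusion(y, pred, class_order)
    correct = int(np.trace(conf.loc[class_order, class_order].to_numpy()))
    return CvReport(
        fold_accuracies=[],
        accuracy=100.0 * correct / len(y),
        confusion=conf,
        seed=seed,
        k=None,
        classifier=spec.kind,
        mode=spec.mode,
    )
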