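"""Correlation-based feature selection (CFS) with greedy stepwise search.

A subset S of k features is scored by Hall's merit

    merit(S) = k * mean|r_cf| / sqrt(k + k (k-1) * mean|r_ff|)

where r_cf is the feature-class correlation and r_ff the pairwise
feature-feature correlation: good subsets correlate with the class and
not with each other. Search is forward greedy: starting empty, add the
feature that maximizes merit until no addition improves it.

The class correlation for a binary class is the point-biserial (Pearson)
correlation, signed; for more classes the default is the mean absolute
point-biserial over one-vs-rest binarizations. A symmetric-uncertainty
variant (entropy-based, on equal-width discretized features) is available
behind the ``method`` switch.

The module also carries the published fixed feature subsets used as
alternative classifier inputs (three-class CFS result, two-class CFS
result, the five features most class-correlated, and the complex
depressive-question-only set).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import SCHEMA

__all__ = [
    "CfsResult",
    "NamedSubset",
    "NAMED_SUBSETS",
    "class_correlation",
    "cfs_merit",
    "greedy_stepwise",
    "named_subset",
]


@dataclass(frozen=True)
class CfsResult:
    selected: tuple[str, ...]
    merit: float
    class_correlations: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected": list(self.selected),
                "merit": self.merit,
                "class_correlations": self.class_correlations,
            }
        )


@dataclass(frozen=True)
class NamedSubset:
    name: str
    features: tuple[str, ...]


NAMED_SUBSETS: dict[str, NamedSubset] = {
    "three_class_cfs": NamedSubset(
        "three_class_cfs",
        ("DS", "2DS-c", "2DS-d", "VAS", "MD-time 2DS-d", "MD-time VAS"),
    ),
    "two_class_cfs": NamedSubset(
        "two_class_cfs",
        (
            "DS",
            "2DS-d",
            "2DS-c",
            "VAS",
            "IT 2EX-d",
            "IT 2EX-c",
            "RT 2EX-c",
            "MD-time",
            "MD-time DS",
            "MD-time 2DS-d",
            "MD-time DS&EX-c",
            "MD-time VAS",
            "a_y",
            "y-flip DS",
        ),
    ),
    "top5_correlated": NamedSubset(
        "top5_correlated",
        ("DS", "2DS-c", "VAS", "DS&EX-c", "MD-time DS"),
    ),
    "complex_DS_only": NamedSubset(
        "complex_DS_only",
        (
            "2DS-c",
            "2DS-d",
            "IT 2DS-c",
            "IT 2DS-d",
            "MD-time 2DS-c",
            "MD-time 2DS-d",
            "RT 2DS-c",
            "RT 2DS-d",
            "MD 2DS-c",
            "MD 2DS-d",
            "AUC 2DS-c",
            "AUC 2DS-d",
            "x-flip 2DS-c",
            "x-flip 2DS-d",
            "y-flip 2DS-c",
            "y-flip 2DS-d",
        ),
    ),
}


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        return 0.0
    return float(a @ b) / denom


def _symmetric_uncertainty(x: np.ndarray, y_codes: np.ndarray, bins: int = 10) -> float:
    """SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y)) with X equal-width discretized."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return 0.0
    xb = np.clip(((x - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    joint = pd.crosstab(xb, y_codes).to_numpy(dtype=float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / (px @ py), 1.0)
        mi = float(np.sum(p * np.log2(ratio)))
        hx = -float(np.sum(px[px > 0] * np.log2(px[px > 0])))
        hy = -float(np.sum(py[py > 0] * np.log2(py[py > 0])))
    if hx + hy == 0:
        return 0.0
    return float(2.0 * mi / (hx + hy))


def class_correlation(values: np.ndarray, labels: np.ndarray, method: str = "point_biserial") -> float:
    """Correlation between a feature and the class.

    Binary class: signed point-biserial correlation. More classes: mean
    absolute point-biserial over one-vs-rest binarizations. ``method=
    'symmetric_uncertainty'`` switches to the entropy-based measure.
    Zero-variance features return 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 distinct labels")
    if np.all(values == values[0]):
        return 0.0
    if method == "symmetric_uncertainty":
        codes = np.searchsorted(classes, labels)
        return _symmetric_uncertainty(values, codes)
    if method != "point_biserial":
        raise ValueError(f"unknown correlation method {method!r}")
    if len(classes) == 2:
        return _pearson(values, (labels == classes[1]).astype(float))
    return float(np.mean([abs(_pearson(values, (labels == c).astype(float))) for c in classes]))


def cfs_merit(
    subset: list[str],
    table: pd.DataFrame,
    labels: np.ndarray,
    method: str = "point_biserial",
) -> float:
    """Hall's CFS merit of a feature subset."""
    if not subset:
        raise ValueError("subset must be nonempty")
    labels = np.asarray(labels)
    k = len(subset)
    r_cf = np.mean(
        [abs(class_correlation(table[f].to_numpy(dtype=float), labels, method)) for f in subset]
    )
    if k == 1:
        return float(r_cf)
    r_ff = []
    for i in range(k):
        for j in range(i + 1, k):
            r_ff.append(
                abs(
                    _pearson(
                        table[subset[i]].to_numpy(dtype=float),
                        table[subset[j]].to_numpy(dtype=float),
                    )
                )
            )
    rff = float(np.mean(r_ff))
    return float(k * r_cf / math.sqrt(k + k * (k - 1) * rff))


def greedy_stepwise(
    table: pd.DataFrame,
    labels: np.ndarray,
    features: list[str] | None = None,
    method: str = "point_biserial",
) -> CfsResult:
    """Forward greedy CFS: add the merit-maximizing feature until no
    addition improves the merit. Ties break by schema (column) order."""
    if features is None:
        features = [c for c in table.columns if c not in ("participant_id", "label")]
    if not features:
        raise ValueError("need at least one candidate feature")
    labels = np.asarray(labels)
    corrs = {
        f: class_correlation(table[f].to_numpy(dtype=float), labels, method) for f in features
    }
    selected: list[str] = []
    best_merit = -np.inf
    while True:
        best_add, best_new = None, best_merit
        for f in features:
            if f in selected:
                continue
            m = cfs_merit(selected + [f], table, labels, method)
            if m > best_new + 1e-12:
                best_add, best_new = f, m
        if best_add is None:
            break
        selected.append(best_add)
        best_merit = best_new
    return CfsResult(tuple(selected), float(best_merit), corrs)


def named_subset(name: str) -> NamedSubset:
    """One of the published fixed feature subsets."""
    if name not in NAMED_SUBSETS:
        raise ValueError(f"unknown subset name {name!r}; known: {sorted(NAMED_SUBSETS)}")
    sub = NAMED_SUBSETS[name]
    assert all(f in SCHEMA.names for f in sub.features)
    return sub
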