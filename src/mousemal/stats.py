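"""Univariate group comparisons: one-way ANOVA with omega-squared effect
size and Tukey HSD post hoc pairwise differences.

Omega-squared is reported rather than eta-squared because it corrects the
upward bias of the sample effect size:

    omega_sq = (SS_between - df_between * MS_within) / (SS_total + MS_within)

clamped below at zero. Tukey-adjusted p-values come from the studentized
range distribution with Tukey-Kramer standard errors; both the classic q
statistic and a t-style statistic (mean difference / SE of the difference
with pooled within-group variance) are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "group_summary",
    "oneway_anova",
    "tukey_hsd",
    "transitivity_check",
    "anova_table",
    "tukey_table",
]


@dataclass(frozen=True)
class AnovaResult:
    feature: str
    f: float
    df_between: int
    df_within: int
    p: float
    omega_sq: float
    omega_clamped: bool = False
    infinite_f: bool = False


@dataclass(frozen=True)
class PairwiseResult:
    feature: str
    pair: tuple[str, str]
    mean_difference: float
    statistic: float  # t-style: difference / SE(difference)
    q: float  # studentized range statistic
    p_adjusted: float


def group_summary(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Per-group mean and SD for every feature column.

    Single-participant groups get SD 0 with a ``degenerate`` flag column.
    """
    if features is None:
        features = [c for c in table.columns if c not in ("participant_id", "label")]
    rows = []
    for label, grp in table.groupby("label", sort=False):
        if len(grp) == 0:
            raise ValueError(f"empty group {label!r}")
        for feat in features:
            vals = grp[feat].to_numpy(dtype=float)
            degenerate = len(vals) < 2
            rows.append(
                {
                    "label": label,
                    "feature": feat,
                    "mean": float(np.mean(vals)),
                    "sd": 0.0 if degenerate else float(np.std(vals, ddof=1)),
                    "n": len(vals),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def oneway_anova(groups: list[np.ndarray], feature: str = "") -> AnovaResult:
    """One-way fixed-effects ANOVA from sums of squares.

    Zero within-group variance with unequal means yields an infinite F
    with a flag; negative omega-squared estimates are clamped to 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    ss_total = ss_between + ss_within
    df_b, df_w = k - 1, n_total - k
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        if ss_between > 0:
            return AnovaResult(feature, math.inf, df_b, df_w, 0.0, 1.0, False, True)
        return AnovaResult(feature, 0.0, df_b, df_w, 1.0, 0.0, True, False)
    f = (ss_between / df_b) / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    omega = (ss_between - df_b * ms_w) / (ss_total + ms_w)
    clamped = omega < 0
    return AnovaResult(feature, float(f), df_b, df_w, p, max(float(omega), 0.0), clamped, False)


def tukey_hsd(
    groups: dict[str, np.ndarray], feature: str = ""
) -> list[PairwiseResult]:
    """Tukey HSD over all unordered group pairs.

    Uses the pooled within-group mean square; adjusted p-values from the
    studentized range distribution with the Tukey-Kramer SE for unequal n.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[l], dtype=float) for l in labels]
    if len(labels) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 values each")
    k = len(labels)
    df_w = sum(len(a) for a in arrays) - k
    ms_w = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays) / df_w
    out = []
    for (i, la), (j, lb) in combinations(enumerate(labels), 2):
        a, b = arrays[i], arrays[j]
        diff = float(a.mean() - b.mean())
        se_t = math.sqrt(ms_w * (1.0 / len(a) + 1.0 / len(b))) if ms_w > 0 else 0.0
        se_q = math.sqrt(ms_w / 2.0 * (1.0 / len(a) + 1.0 / len(b))) if ms_w > 0 else 0.0
        if se_q == 0.0:
            q = math.inf if diff != 0 else 0.0
            t = math.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se_q
            t = diff / se_t
            p = float(sps.studentized_range.sf(q, k, df_w))
        out.append(PairwiseResult(feature, (la, lb), diff, t, q, p))
    return out


def transitivity_check(
    diff_ab: float, diff_ac: float, diff_bc: float, tol: float = 0.02
) -> bool:
    """Internal consistency of three pairwise differences.

    For groups (A, B, C): diff(A,B) must equal diff(A,C) − diff(B,C) up to
    ``tol`` (printed tables are rounded to 2 decimals).
    """
    for v in (diff_ab, diff_ac, diff_bc):
        if v is None or not np.isfinite(v):
            raise ValueError("all three pairwise differences are required")
    return bool(abs(diff_ab - (diff_ac - diff_bc)) <= tol + 1e-12)


def anova_table(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Run the per-feature one-way ANOVA across groups; tidy results."""
    if features is None:
        features = [c for c in table.columns if c not in ("participant_id", "label")]
    labels = list(dict.fromkeys(table["label"]))
    rows = []
    for feat in features:
        groups = [table.loc[table["label"] == l, feat].to_numpy(dtype=float) for l in labels]
        r = oneway_anova(groups, feature=feat)
        rows.append(
            {
                "feature": feat,
                "F": r.f,
                "df_between": r.df_between,
                "df_within": r.df_within,
                "p": r.p,
                "omega_sq": r.omega_sq,
            }
        )
    return pd.DataFrame(rows)


def tukey_table(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Tukey post hoc for every feature; tidy pairwise results."""
    if features is None:
        features = [c for c in table.columns if c not in ("participant_id", "label")]
    labels = list(dict.fromkeys(table["label"]))
    rows = []
    for feat in features:
        groups = {l: table.loc[table["label"] == l, feat].to_numpy(dtype=float) for l in labels}
        for r in tukey_hsd(groups, feature=feat):
            rows.append(
                {
                    "feature": feat,
                    "group_a": r.pair[0],
                    "group_b": r.pair[1],
                    "mean_difference": r.mean_difference,
                    "t": r.statistic,
                    "q": r.q,
                    "p_adjusted": r.p_adjusted,
                }
            )
    return pd.DataFrame(rows)
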