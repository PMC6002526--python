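"""Aggregation of per-trial metrics into the 83-feature participant vector.

The schema is: the seven trajectory metrics (IT, RT, MD-time, MD, AUC,
x-flip, y-flip) averaged within each of the nine question types and
overall (7 × 10 = 70), the four overall velocity/acceleration means
(v_x, v_y, a_x, a_y), the six symptom-endorsement counts (DS, 2DS-d,
2DS-c, DS&EX-d, DS&EX-c, VAS) and the three control-error counts
(EX, 2EX-d, 2EX-c) — 83 features in total. Per-type features are named
"<metric> <category>" (e.g. "MD-time 2DS-d"); overall metrics carry the
bare metric name; count features carry the bare category code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import TrialFeatures
from .protocol import CONTROL_CATEGORIES, SYMPTOM_CATEGORIES, StimulusSet, truthful_answer

__all__ = [
    "METRICS",
    "FeatureSchema",
    "SCHEMA",
    "ParticipantFeatures",
    "symptom_counts",
    "control_errors",
    "aggregate",
    "feature_table",
]

#: trajectory metrics averaged per question type and overall
METRICS = ("IT", "RT", "MD-time", "MD", "AUC", "x-flip", "y-flip")

_METRIC_ATTR = {
    "IT": "it_ms",
    "RT": "rt_ms",
    "MD-time": "md_time_ms",
    "MD": "md",
    "AUC": "auc",
    "x-flip": "x_flip",
    "y-flip": "y_flip",
}

_TYPE_ORDER = ("EX", "DS", "VAS", "2DS-d", "2DS-c", "DS&EX-d", "DS&EX-c", "2EX-d", "2EX-c")


@dataclass(frozen=True)
class FeatureSchema:
    """The fixed, ordered 83-feature name list."""

    names: tuple[str, ...] = field(default_factory=tuple)

    @staticmethod
    def build() -> "FeatureSchema":
        names: list[str] = []
        for m in METRICS:
            names.append(m)  # overall mean
            names.extend(f"{m} {t}" for t in _TYPE_ORDER)
        names.extend(["v_x", "v_y", "a_x", "a_y"])
        names.extend(SYMPTOM_CATEGORIES)
        names.extend(CONTROL_CATEGORIES)
        return FeatureSchema(tuple(names))

    def __len__(self) -> int:
        return len(self.names)

    def parse(self, name: str) -> tuple[str, str]:
        """Split a feature name into (kind, scope).

        kind is a metric, "velocity", "count" or "error"; scope is the
        question-type code or "overall".
        """
        if name in ("v_x", "v_y", "a_x", "a_y"):
            return "velocity", "overall"
        if name in SYMPTOM_CATEGORIES:
            return "count", name
        if name in CONTROL_CATEGORIES:
            return "error", name
        parts = name.split(" ", 1)
        if parts[0] in METRICS:
            return parts[0], parts[1] if len(parts) > 1 else "overall"
        raise ValueError(f"unknown feature name: {name!r}")

    def to_json(self) -> str:
        return json.dumps({"n_features": len(self.names), "names": list(self.names)})


SCHEMA = FeatureSchema.build()
assert len(SCHEMA) == 83


@dataclass
class ParticipantFeatures:
    """One participant's 83-feature vector plus metadata."""

    participant_id: str
    label: str
    values: dict[str, float]

    def __post_init__(self):
        missing = set(SCHEMA.names) - set(self.values)
        extra = set(self.values) - set(SCHEMA.names)
        if missing or extra:
            raise ValueError(f"feature vector does not match schema (missing={sorted(missing)[:3]}, extra={sorted(extra)[:3]})")

    def as_series(self) -> pd.Series:
        return pd.Series({n: self.values[n] for n in SCHEMA.names}, name=self.participant_id)


def _check_responses(responses: dict[str, bool], stimulus_set: StimulusSet) -> None:
    for q in stimulus_set:
        if q.id not in responses:
            raise ValueError(f"missing response for question {q.id!r}")


def symptom_counts(responses: dict[str, bool], stimulus_set: StimulusSet) -> dict[str, int]:
    """Number of 'yes' responses per symptom-bearing category."""
    _check_responses(responses, stimulus_set)
    counts = {c: 0 for c in SYMPTOM_CATEGORIES}
    for q in stimulus_set:
        code = q.category.code
        if code in counts and responses[q.id]:
            counts[code] += 1
    return counts


def control_errors(responses: dict[str, bool], stimulus_set: StimulusSet) -> dict[str, int]:
    """Number of responses differing from the answer key, per control category.

    Control keys are identical for healthy and depressed profiles, so the
    healthy key is used.
    """
    _check_responses(responses, stimulus_set)
    errors = {c: 0 for c in CONTROL_CATEGORIES}
    for q in stimulus_set:
        code = q.category.code
        if code in errors and responses[q.id] != truthful_answer(q, depressed=False):
            errors[code] += 1
    return errors


def aggregate(
    trial_features: dict[str, TrialFeatures],
    responses: dict[str, bool],
    stimulus_set: StimulusSet,
    participant_id: str = "p0",
    label: str = "unknown",
) -> ParticipantFeatures:
    """Build the 83-feature vector for one participant.

    Trials missing from ``trial_features`` (e.g. excluded degenerate
    trajectories) are dropped from the metric means with a warning; counts
    are computed from responses and are unaffected.
    """
    import warnings

    _check_responses(responses, stimulus_set)
    present = [q for q in stimulus_set if q.id in trial_features]
    dropped = len(stimulus_set) - len(present)
    if dropped:
        warnings.warn(f"{dropped} trial(s) missing kinematic features; dropped from means")

    values: dict[str, float] = {}
    by_type: dict[str, list[TrialFeatures]] = {t: [] for t in _TYPE_ORDER}
    for q in present:
        by_type[q.category.code].append(trial_features[q.id])
    all_tf = [trial_features[q.id] for q in present]

    for m in METRICS:
        attr = _METRIC_ATTR[m]
        values[m] = float(np.mean([getattr(tf, attr) for tf in all_tf])) if all_tf else np.nan
        for t in _TYPE_ORDER:
            group = by_type[t]
            if not group:
                if stimulus_set.counts.get(t, 0) > 0:
                    raise ValueError(f"no usable trials for category {t!r} with nonzero configured count")
                values[f"{m} {t}"] = np.nan
            else:
                values[f"{m} {t}"] = float(np.mean([getattr(tf, attr) for tf in group]))

    for name, attr in (("v_x", "v_x"), ("v_y", "v_y"), ("a_x", "a_x"), ("a_y", "a_y")):
        values[name] = float(np.mean([getattr(tf, attr) for tf in all_tf])) if all_tf else np.nan

    values.update({k: float(v) for k, v in symptom_counts(responses, stimulus_set).items()})
    values.update({k: float(v) for k, v in control_errors(responses, stimulus_set).items()})
    return ParticipantFeatures(participant_id=participant_id, label=label, values=values)


def feature_table(participants: list[ParticipantFeatures]) -> pd.DataFrame:
    """Tidy table: one row per participant, 83 feature columns + id + label."""
    rows = []
    for p in participants:
        row = {"participant_id": p.participant_id, "label": p.label}
        row.update({n: p.values[n] for n in SCHEMA.names})
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", "label", *SCHEMA.names])
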