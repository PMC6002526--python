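"""Stimulus protocol: question categories, answer keys and the SIMS-AF rule.

The task presents yes/no questions drawn from nine categories. Simple
categories carry one piece of information (a control statement about the
experimental situation, a typical depressive symptom, or a very atypical
symptom); complex categories conjoin two pieces, and the keyed answer is
"yes" iff both components are true. Complex questions raise the cognitive
load of respondents who must maintain a fabricated symptom profile, which
is why they carry most of the discriminative signal downstream.

Category codes
--------------
EX       control statements about the experimental condition (always true)
DS       typical depressive symptoms
VAS      very atypical symptoms (SIMS-AF malingering screen items)
2DS-c    two concordant depressive symptoms (both typical)
2DS-d    two discordant symptoms (one typical, one atypical)
DS&EX-c  depressive symptom + true control statement
DS&EX-d  depressive symptom + false control statement
2EX-c    two true control statements
2EX-d    one true + one false control statement
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Complexity",
    "QuestionCategory",
    "QuestionSpec",
    "StimulusSet",
    "CATEGORIES",
    "DEFAULT_COUNTS",
    "SYMPTOM_CATEGORIES",
    "CONTROL_CATEGORIES",
    "build_stimulus_set",
    "truthful_answer",
    "sims_af_flag",
]


class Complexity(str, Enum):
    SIMPLE = "simple"
    COMPLEX = "complex"


@dataclass(frozen=True)
class QuestionCategory:
    """One of the nine question types of the task."""

    code: str
    complexity: Complexity
    default_count: int
    # truth value of each component proposition for a healthy responder and
    # for a genuinely depressed responder; the keyed answer is the
    # conjunction of the components.
    components_healthy: tuple[bool, ...]
    components_depressed: tuple[bool, ...]

    def key(self, depressed: bool) -> bool:
        comps = self.components_depressed if depressed else self.components_healthy
        return all(comps)


# Component truth tables. Typical depressive symptoms (DS) are true for the
# depressed profile only; very atypical symptoms (VAS) are true for neither
# (they are the malingering screen); control statements (EX) are true for
# everyone except the deliberately false halves of the discordant controls.
CATEGORIES: dict[str, QuestionCategory] = {
    c.code: c
    for c in [
        QuestionCategory("EX", Complexity.SIMPLE, 5, (True,), (True,)),
        QuestionCategory("DS", Complexity.SIMPLE, 10, (False,), (True,)),
        QuestionCategory("VAS", Complexity.SIMPLE, 15, (False,), (False,)),
        QuestionCategory("2DS-d", Complexity.COMPLEX, 15, (False, False), (True, False)),
        QuestionCategory("2DS-c", Complexity.COMPLEX, 15, (False, False), (True, True)),
        QuestionCategory("DS&EX-d", Complexity.COMPLEX, 5, (False, False), (True, False)),
        QuestionCategory("DS&EX-c", Complexity.COMPLEX, 5, (False, True), (True, True)),
        QuestionCategory("2EX-d", Complexity.COMPLEX, 3, (True, False), (True, False)),
        QuestionCategory("2EX-c", Complexity.COMPLEX, 3, (True, True), (True, True)),
    ]
}

DEFAULT_COUNTS: dict[str, int] = {c: CATEGORIES[c].default_count for c in CATEGORIES}

#: categories whose "yes" responses are counted as reported symptoms
SYMPTOM_CATEGORIES = ("DS", "2DS-d", "2DS-c", "DS&EX-d", "DS&EX-c", "VAS")
#: control categories whose wrong answers are counted as errors
CONTROL_CATEGORIES = ("EX", "2EX-d", "2EX-c")

#: SIMS-AF screening rule: flagged if more than this many atypical symptoms
SIMS_AF_CUTOFF = 5


@dataclass(frozen=True)
class QuestionSpec:
    """A single item: its category and its keyed answers."""

    id: str
    category: QuestionCategory
    truthful_answer_healthy: bool
    truthful_answer_depressed: bool


@dataclass
class StimulusSet:
    """An ordered, shuffled collection of questions."""

    questions: list[QuestionSpec]
    seed: int
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.questions)

    def __iter__(self):
        return iter(self.questions)

    def by_category(self, code: str) -> list[QuestionSpec]:
        return [q for q in self.questions if q.category.code == code]

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["id", "category", "complexity", "key_healthy", "key_depressed"])
        for q in self.questions:
            w.writerow(
                [
                    q.id,
                    q.category.code,
                    q.category.complexity.value,
                    "yes" if q.truthful_answer_healthy else "no",
                    "yes" if q.truthful_answer_depressed else "no",
                ]
            )
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "counts": self.counts,
                "questions": [
                    {
                        "id": q.id,
                        "category": q.category.code,
                        "key_healthy": q.truthful_answer_healthy,
                        "key_depressed": q.truthful_answer_depressed,
                    }
                    for q in self.questions
                ],
            }
        )


def build_stimulus_set(
    counts_per_category: dict[str, int] | None = None, seed: int = 0
) -> StimulusSet:
    """Build a shuffled stimulus set with the requested per-category counts.

    Answer keys follow the conjunction semantics of each category; the
    presentation order is a uniform shuffle driven by ``seed``.
    """
    counts = dict(DEFAULT_COUNTS if counts_per_category is None else counts_per_category)
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown category code(s): {sorted(unknown)}")
    if any(n < 0 for n in counts.values()):
        raise ValueError("category counts must be non-negative")

    questions: list[QuestionSpec] = []
    for code in CATEGORIES:  # stable schema order
        cat = CATEGORIES[code]
        for i in range(counts.get(code, 0)):
            questions.append(
                QuestionSpec(
                    id=f"{code}-{i + 1:02d}",
                    category=cat,
                    truthful_answer_healthy=cat.key(depressed=False),
                    truthful_answer_depressed=cat.key(depressed=True),
                )
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(questions))
    questions = [questions[i] for i in order]
    return StimulusSet(questions=questions, seed=seed, counts=counts)


def truthful_answer(question: QuestionSpec, depressed: bool) -> bool:
    """Keyed answer of ``question`` for the given clinical state."""
    return question.truthful_answer_depressed if depressed else question.truthful_answer_healthy


def sims_af_flag(vas_count: int) -> bool:
    """SIMS-AF screen: flag malingering if more than five atypical symptoms."""
    if vas_count < 0:
        raise ValueError("vas_count must be non-negative")
    return vas_count > SIMS_AF_CUTOFF
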