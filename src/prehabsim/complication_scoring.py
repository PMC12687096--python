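"""Clavien-Dindo complication grading and the Comprehensive Complication Index.

The Clavien-Dindo classification grades a single postoperative complication
on an ordinal scale from I (any deviation from the normal postoperative
course) to V (death).  The Comprehensive Complication Index (CCI) summarizes
*all* of a patient's graded complications on a continuous 0-100 scale using
published severity weights derived from patient and physician reference
ratings: 0 means an uneventful course and 100 means death.

The CCI for a patient with complications of weights :math:`w_1, \\dots, w_k`
is

.. math::  \\mathrm{CCI} = \\min\\!\\left(100,\\ \\frac{\\sqrt{w_1 + \\dots + w_k}}{2}\\right)

with any grade V complication mapping directly to the scale maximum of 100.
Single-complication values reproduce the published calculator: I -> 8.7,
II -> 20.9, IIIa -> 26.2, IIIb -> 33.7, IVa -> 42.4, IVb -> 46.2, V -> 100.

Two blinded coders may grade each complication independently; this module
also provides the adjudication rules used to merge their assessments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "GRADES",
    "CCI_WEIGHTS",
    "ComplicationEvent",
    "AdjudicationRecord",
    "adjudicate_grades",
    "comprehensive_complication_index",
    "summarize_morbidity",
    "parse_grade_list",
    "format_grade_list",
]

#: Canonical Clavien-Dindo grades, in severity order.
GRADES: tuple[str, ...] = ("I", "II", "IIIa", "IIIb", "IVa", "IVb", "V")

#: Published CCI severity weights per grade (the weight of one complication).
#: sqrt(weight)/2 gives the single-complication index value.
CCI_WEIGHTS: Mapping[str, float] = {
    "I": 300.0,
    "II": 1750.0,
    "IIIa": 2750.0,
    "IIIb": 4550.0,
    "IVa": 7200.0,
    "IVb": 8550.0,
    "V": 39940.0,
}

_GRADE_RANK = {g: i for i, g in enumerate(GRADES)}

ADJUDICATION_RULES = ("consensus_flag", "take_higher", "take_lower")


def _check_grade(grade: str) -> str:
    if grade not in _GRADE_RANK:
        raise ValueError(f"invalid Clavien-Dindo grade {grade!r}; expected one of {GRADES}")
    return grade


@dataclass(frozen=True)
class ComplicationEvent:
    """A single postoperative complication."""

    grade: str
    timing: str = "30d"  # {"discharge", "30d"}
    type_label: str = ""

    def __post_init__(self) -> None:
        _check_grade(self.grade)
        if self.timing not in ("discharge", "30d"):
            raise ValueError(f"timing must be 'discharge' or '30d', got {self.timing!r}")


@dataclass
class AdjudicationRecord:
    """Two coders' grades for one complication and the merged outcome."""

    coder1_grade: str
    coder2_grade: str
    resolution_rule: str
    resolved_grade: Optional[str] = None

    @property
    def resolved(self) -> bool:
        return self.resolved_grade is not None


def adjudicate_grades(g1: str, g2: str, rule: str = "take_higher") -> AdjudicationRecord:
    """Merge two independent coders' grades for the same complication.

    Equal grades pass through under every rule.  Disagreements are resolved
    by taking the higher grade (conservative default), the lower grade, or —
    under ``consensus_flag`` — left unresolved for human review, in which
    case ``resolved_grade`` is ``None``.
    """
    _check_grade(g1)
    _check_grade(g2)
    if rule not in ADJUDICATION_RULES:
        raise ValueError(f"unknown adjudication rule {rule!r}; expected one of {ADJUDICATION_RULES}")
    rec = AdjudicationRecord(coder1_grade=g1, coder2_grade=g2, resolution_rule=rule)
    if g1 == g2:
        rec.resolved_grade = g1
    elif rule == "take_higher":
        rec.resolved_grade = g1 if _GRADE_RANK[g1] > _GRADE_RANK[g2] else g2
    elif rule == "take_lower":
        rec.resolved_grade = g1 if _GRADE_RANK[g1] < _GRADE_RANK[g2] else g2
    # consensus_flag: leave unresolved
    return rec


def comprehensive_complication_index(events: Iterable) -> float:
    """CCI over all of one patient's complications, in [0, 100].

    ``events`` may contain :class:`ComplicationEvent` objects or bare grade
    strings.  No events gives 0; any grade V (death) gives 100; otherwise
    the square-root-sum-of-weights formula applies, capped at 100.
    """
    grades = [e.grade if isinstance(e, ComplicationEvent) else _check_grade(e) for e in events]
    if not grades:
        return 0.0
    if "V" in grades:
        return 100.0
    total = sum(CCI_WEIGHTS[g] for g in grades)
    return min(100.0, math.sqrt(total) / 2.0)


def parse_grade_list(text) -> list[str]:
    """Parse the compact ``"II;II;IIIa"`` cohort-table serialization."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return []
    text = str(text).strip()
    if not text:
        return []
    return [_check_grade(g.strip()) for g in text.split(";")]


def format_grade_list(grades: Sequence[str]) -> str:
    return ";".join(_check_grade(g) for g in grades)


def summarize_morbidity(cohort: pd.DataFrame) -> dict:
    """Per-arm postoperative morbidity summary.

    For each arm: the proportion of participants with at least one
    complication, event counts and participant-presence proportions per
    grade, the tally of each participant's highest grade (``"none"`` for
    event-free participants), and the CCI distribution (participants without
    events contribute CCI 0).

    ``cohort`` needs columns ``arm`` and ``complications`` (the grade-list
    serialization).  An empty arm raises ``ValueError``.
    """
    if "arm" not in cohort.columns or "complications" not in cohort.columns:
        raise ValueError("cohort must have 'arm' and 'complications' columns")
    out: dict[str, dict] = {}
    for arm, group in cohort.groupby("arm", sort=True):
        n = len(group)
        if n == 0:
            raise ValueError(f"arm {arm!r} is empty")
        grade_lists = [parse_grade_list(x) for x in group["complications"]]
        n_affected = sum(1 for g in grade_lists if g)
        event_counts = {g: 0 for g in GRADES}
        presence = {g: 0 for g in GRADES}
        highest: dict[str, int] = {"none": 0, **{g: 0 for g in GRADES}}
        ccis = []
        for grades in grade_lists:
            for g in grades:
                event_counts[g] += 1
            for g in set(grades):
                presence[g] += 1
            top = max(grades, key=_GRADE_RANK.get) if grades else "none"
            highest[top] += 1
            ccis.append(comprehensive_complication_index(grades))
        cci = pd.Series(ccis)
        out[str(arm)] = {
            "n": n,
            "n_affected": n_affected,
            "prop_any_complication": n_affected / n,
            "n_events": sum(event_counts.values()),
            "events_per_grade": event_counts,
            "prop_with_grade": {g: presence[g] / n for g in GRADES},
            "highest_grade_tally": highest,
            "cci": {
                "mean": float(cci.mean()),
                "median": float(cci.median()),
                "q1": float(cci.quantile(0.25)),
                "q3": float(cci.quantile(0.75)),
                "max": float(cci.max()),
            },
        }
    if not out:
        raise ValueError("cohort is empty")
    return out
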