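"""Covariate-adaptive treatment allocation by Pocock-Simon minimization.

Each incoming participant is assigned to the arm that minimizes the summed
within-factor-level imbalance (the "range" metric: the absolute difference in
arm counts at the participant's level of each minimization factor), with a
configurable random element so that allocation is never fully deterministic.

Two interpretations of the random element are supported:

``coin_flip`` (default)
    With probability ``random_element`` the minimization rule is ignored and
    the arm is drawn by a fair coin; otherwise the minimizing arm is taken
    (ties broken by a fair coin).

``biased_coin``
    The minimizing arm is taken with probability ``1 - random_element`` and
    the other arm with probability ``random_element``; ties are fair coins.

State can be persisted to and restored from JSON so that a long-running
allocation sequence can span multiple processes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MinimizationState",
    "imbalance_after",
    "assign_arm",
]


@dataclass
class MinimizationState:
    """Running allocation counts for Pocock-Simon minimization.

    Parameters
    ----------
    factors
        Mapping from factor name to the sequence of admissible levels,
        e.g. ``{"performance_status": ("0", "1-2"), "age_stratum": ("<70", ">=70")}``.
    arms
        The two arm labels, in a fixed order.
    random_element
        Probability ``q`` in [0, 1] governing the random component of each
        assignment (see module docstring).
    method
        ``"coin_flip"`` or ``"biased_coin"``.
    """

    factors: Mapping[str, Sequence[str]]
    arms: tuple[str, str] = ("intervention", "usual_care")
    random_element: float = 0.2
    method: str = "coin_flip"
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.random_element <= 1.0:
            raise ValueError(f"random_element must be in [0, 1], got {self.random_element}")
        if len(self.arms) != 2 or len(set(self.arms)) != 2:
            raise ValueError("exactly two distinct arm labels are required")
        if self.method not in ("coin_flip", "biased_coin"):
            raise ValueError(f"unknown method {self.method!r}")
        if not self.factors:
            raise ValueError("at least one minimization factor is required")
        self.factors = {f: tuple(str(l) for l in levels) for f, levels in self.factors.items()}
        for factor, levels in self.factors.items():
            for level in levels:
                for arm in self.arms:
                    self.counts.setdefault(self._key(factor, level, arm), 0)
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be nonnegative")

    @staticmethod
    def _key(factor: str, level: str, arm: str) -> str:
        return f"{factor}|{level}|{arm}"

    def count(self, factor: str, level: str, arm: str) -> int:
        return self.counts[self._key(factor, level, arm)]

    def arm_totals(self) -> dict[str, int]:
        """Total participants allocated per arm (from the first factor's margins)."""
        first = next(iter(self.factors))
        return {
            arm: sum(self.count(first, level, arm) for level in self.factors[first])
            for arm in self.arms
        }

    def _check_levels(self, participant_levels: Mapping[str, str]) -> None:
        for factor, levels in self.factors.items():
            if factor not in participant_levels:
                raise ValueError(f"missing level for factor {factor!r}")
            if str(participant_levels[factor]) not in levels:
                raise ValueError(
                    f"unknown level {participant_levels[factor]!r} for factor {factor!r}"
                )
        for factor in participant_levels:
            if factor not in self.factors:
                raise ValueError(f"unknown factor {factor!r}")

    def record(self, participant_levels: Mapping[str, str], arm: str) -> None:
        """Add one participant with the given factor levels to ``arm``."""
        self._check_levels(participant_levels)
        if arm not in self.arms:
            raise ValueError(f"unknown arm {arm!r}")
        for factor in self.factors:
            self.counts[self._key(factor, str(participant_levels[factor]), arm)] += 1

    # -- JSON persistence -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "factors": {f: list(l) for f, l in self.factors.items()},
                "arms": list(self.arms),
                "random_element": self.random_element,
                "method": self.method,
                "counts": self.counts,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MinimizationState":
        doc = json.loads(text)
        return cls(
            factors={f: tuple(l) for f, l in doc["factors"].items()},
            arms=tuple(doc["arms"]),
            random_element=doc["random_element"],
            method=doc["method"],
            counts=dict(doc["counts"]),
        )


def imbalance_after(
    state: MinimizationState,
    participant_levels: Mapping[str, str],
    candidate_arm: str,
) -> int:
    """Summed within-level imbalance if the participant joined ``candidate_arm``.

    For every minimization factor the absolute difference between the two
    arms' counts at the participant's level is evaluated *after*
    hypothetically adding the participant to ``candidate_arm``; the score is
    the sum over factors (equal weights).
    """
    state._check_levels(participant_levels)
    if candidate_arm not in state.arms:
        raise ValueError(f"unknown arm {candidate_arm!r}")
    a1, a2 = state.arms
    score = 0
    for factor in state.factors:
        level = str(participant_levels[factor])
        c1 = state.count(factor, level, a1) + (1 if candidate_arm == a1 else 0)
        c2 = state.count(factor, level, a2) + (1 if candidate_arm == a2 else 0)
        score += abs(c1 - c2)
    return score


def assign_arm(
    state: MinimizationState,
    participant_levels: Mapping[str, str],
    rng: np.random.Generator,
) -> str:
    """Allocate one participant, update ``state``, and return the arm label."""
    q = state.random_element
    scores = {arm: imbalance_after(state, participant_levels, arm) for arm in state.arms}
    a1, a2 = state.arms
    if scores[a1] == scores[a2]:
        arm = a1 if rng.random() < 0.5 else a2
    else:
        minimizing = a1 if scores[a1] < scores[a2] else a2
        other = a2 if minimizing == a1 else a1
        if state.method == "coin_flip":
            if rng.random() < q:
                arm = a1 if rng.random() < 0.5 else a2
            else:
                arm = minimizing
        else:  # biased_coin
            arm = minimizing if rng.random() < 1.0 - q else other
    state.record(participant_levels, arm)
    return arm
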