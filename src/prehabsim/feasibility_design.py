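"""Design calculations for feasibility progression criteria.

A feasibility trial predefines red/amber/green limits for each progression
criterion.  The design question is: with n participants, what is the power
of a one-sided exact binomial test to show that a proportion criterion is
above its upper red limit, when the truth sits in the green zone?

The test is the conservative non-randomized exact test: reject when the
observed success count reaches the smallest k* whose upper-tail probability
under the red-limit null is at most alpha.  Power is the upper-tail
probability of k* under the green-zone alternative, both by exact summation
of the binomial mass.  Collective power across independent criteria is
combined by a strategy rule (product by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PowerQuery",
    "PowerResult",
    "exact_binomial_power",
    "collective_power",
    "required_sample_size",
]


@dataclass(frozen=True)
class PowerQuery:
    """One-sided exact binomial power query.

    ``p_null`` is the red limit (null proportion), ``p_alt`` the green-zone
    alternative, ``alpha`` the one-sided significance level.
    """

    n: int
    p_null: float
    p_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("p_null", "p_alt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


class PowerResult(NamedTuple):
    power: float
    k_star: int
    attained_size: float


def exact_binomial_power(q: PowerQuery) -> PowerResult:
    """Exact power of the one-sided binomial test at the critical value k*.

    k* is the smallest success count whose upper-tail probability under
    ``p_null`` does not exceed ``alpha`` (k* = n + 1, a never-rejecting
    test with power 0, if no such count exists).
    """
    k = np.arange(q.n + 2)
    upper_tail_null = stats.binom.sf(k - 1, q.n, q.p_null)  # P(X >= k | p_null)
    feasible = np.flatnonzero(upper_tail_null <= q.alpha)
    k_star = int(feasible[0])
    if k_star > q.n:
        return PowerResult(power=0.0, k_star=k_star, attained_size=0.0)
    power = float(stats.binom.sf(k_star - 1, q.n, q.p_alt))
    return PowerResult(power=power, k_star=k_star,
                       attained_size=float(upper_tail_null[k_star]))


def collective_power(powers: Sequence[float], rule: str = "product") -> float:
    """Combine per-criterion powers into a collective power.

    ``product`` assumes the criteria are assessed on independent data, so
    the probability that every criterion clears its red limit is the product
    of the individual powers.  ``min`` gives the weakest-link bound instead.
    """
    powers = list(powers)
    if not powers:
        raise ValueError("at least one power value is required")
    if any(not 0.0 <= p <= 1.0 for p in powers):
        raise ValueError("powers must be proportions in [0, 1]")
    if rule == "product":
        return float(np.prod(powers))
    if rule == "min":
        return float(min(powers))
    raise ValueError(f"unknown combination rule {rule!r}")


def required_sample_size(
    p_null: float,
    p_alt: float,
    alpha: float = 0.05,
    target_power: float = 0.90,
    n_max: int = 1_000_000,
) -> int:
    """Smallest n whose exact one-sided binomial power reaches the target.

    Exact binomial power is not monotone in n (it saw-tooths as the
    critical value jumps), so the search scans n upward and returns the
    first n with power >= ``target_power``; by construction the power at
    n - 1 is below the target.
    """
    if not p_alt > p_null:
        raise ValueError(f"p_alt ({p_alt}) must exceed p_null ({p_null})")
    if not 0.0 < target_power <= 1.0:
        raise ValueError(f"target_power must be in (0, 1], got {target_power}")
    for n in range(1, n_max + 1):
        if exact_binomial_power(PowerQuery(n, p_null, p_alt, alpha)).power >= target_power:
            return n
    raise RuntimeError(f"no n <= {n_max} attains power {target_power}")
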