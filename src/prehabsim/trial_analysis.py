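"""Effect estimation and feasibility evaluation for the two-arm trial.

Implements the trial's estimators on a cohort table: adherence
classification against the 5 % / 2 % weight-loss thresholds, 2x2 odds
ratios with Woolf log-scale confidence intervals, baseline-adjusted mean
differences (ANCOVA form), progression-criteria traffic-light evaluation
with exact one-sided binomial tests against red limits, and the exploratory
median-split analysis of the Comprehensive Complication Index, under both
intention-to-treat and per-protocol analysis sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .complication_scoring import comprehensive_complication_index, parse_grade_list

__all__ = [
    "TwoByTwoTable",
    "EffectEstimate",
    "ProgressionCriterion",
    "classify_adherence",
    "odds_ratio_2x2",
    "adjusted_mean_difference",
    "evaluate_progression_criteria",
    "median_split_cci_ratio",
    "itt_set",
    "per_protocol_set",
    "adherence_table",
    "participant_cci",
]

ADHERENT_THRESHOLD = 5.0  # % loss for adherence ("5 % or more weight loss")
NONADHERENT_THRESHOLD = 2.0  # % loss below which a participant is nonadherent
Z_95 = 1.959963984540054


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts with exposure on rows and outcome on columns:
    ``a`` exposed-with-outcome, ``b`` exposed-without, ``c`` unexposed-with,
    ``d`` unexposed-without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    def swapped(self) -> "TwoByTwoTable":
        """Simultaneous row and column swap (OR-invariant)."""
        return TwoByTwoTable(a=self.d, b=self.c, c=self.b, d=self.a)


@dataclass(frozen=True)
class EffectEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    scale: str  # {"difference", "ratio", "odds_ratio"}
    n_used: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"interval [{self.ci_low}, {self.ci_high}] does not cover estimate {self.estimate}"
            )

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round(self.estimate, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


@dataclass
class ProgressionCriterion:
    """One feasibility criterion with red/green limits and its observed value.

    Values at or below ``red_limit`` are red (stop); values at or above
    ``green_limit`` are green (go); anything between is amber ("progress
    with changes").
    """

    name: str
    red_limit: float
    green_limit: float
    observed: Optional[float] = None
    unit: str = "proportion"

    def __post_init__(self) -> None:
        if self.red_limit is None or self.green_limit is None:
            raise ValueError(f"criterion {self.name!r}: both limits are required")
        if not self.red_limit < self.green_limit:
            raise ValueError(
                f"criterion {self.name!r}: red_limit ({self.red_limit}) must be below "
                f"green_limit ({self.green_limit})"
            )


def classify_adherence(pct_change: float) -> str:
    """Adherence class from the percentage weight change (negative = loss).

    Loss of 5 % or more is ``adherent``, loss below 2 % is ``nonadherent``,
    anything between is ``intermediate``.
    """
    if not math.isfinite(pct_change):
        raise ValueError(f"pct_change must be finite, got {pct_change}")
    loss = -pct_change
    if loss >= ADHERENT_THRESHOLD:
        return "adherent"
    if loss < NONADHERENT_THRESHOLD:
        return "nonadherent"
    return "intermediate"


def odds_ratio_2x2(table: TwoByTwoTable, correction: bool = False) -> EffectEstimate:
    """Odds ratio with a 95 % Woolf (log-scale) confidence interval.

    With any zero cell the estimate is undefined unless ``correction`` is
    set, in which case 0.5 is added to every cell (Haldane-Anscombe).
    """
    cells = [table.a, table.b, table.c, table.d]
    if 0 in cells:
        if not correction:
            raise ZeroDivisionError(
                "zero cell makes the odds ratio undefined; pass correction=True"
            )
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - Z_95 * se), math.exp(math.log(or_) + Z_95 * se)
    return EffectEstimate(
        estimate=or_, ci_low=lo, ci_high=hi, scale="odds_ratio",
        n_used=int(table.a + table.b + table.c + table.d),
    )


def adjusted_mean_difference(
    outcome: Sequence[float],
    arm: Sequence[str],
    baseline: Sequence[float],
    reference_arm: str = "usual_care",
) -> EffectEstimate:
    """Between-group mean difference adjusted for a baseline covariate.

    Ordinary least squares of the outcome on an arm indicator (1 for the
    non-reference arm) plus the baseline covariate; returns the arm
    coefficient with a normal-approximation 95 % CI.  Rows with missing
    outcome or baseline are dropped, never imputed.
    """
    df = pd.DataFrame({"y": outcome, "arm": arm, "x": baseline}).dropna(subset=["y", "x"])
    arms = sorted(df["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"exactly two arms required, got {arms}")
    if reference_arm not in arms:
        raise ValueError(f"reference arm {reference_arm!r} not present in {arms}")
    counts = df["arm"].value_counts()
    if counts.min() < 2:
        raise ValueError("need at least 2 participants with observed data per arm")
    treated = [a for a in arms if a != reference_arm][0]
    z = (df["arm"] == treated).astype(float)
    if z.nunique() < 2:
        raise ValueError("degenerate design: arm indicator is constant")
    cols = {"arm": z}
    if df["x"].nunique() > 1:  # constant covariate carries no information
        cols["baseline"] = df["x"]
    X = sm.add_constant(pd.DataFrame(cols))
    fit = sm.OLS(df["y"], X).fit()
    est = float(fit.params["arm"])
    se = float(fit.bse["arm"])
    return EffectEstimate(
        estimate=est, ci_low=est - Z_95 * se, ci_high=est + Z_95 * se,
        scale="difference", n_used=len(df),
    )


def evaluate_progression_criteria(
    criteria: Sequence[ProgressionCriterion],
    n_denominators: Optional[dict[str, int]] = None,
) -> dict:
    """Traffic-light report for a set of progression criteria.

    Zones: green if observed >= green limit, red if observed <= red limit
    (the boundary counts as red, conservatively), otherwise amber.  For
    criteria with a denominator supplied in ``n_denominators`` an exact
    one-sided binomial p-value is attached: the probability of observing at
    least the implied success count if the true proportion equaled the red
    limit.
    """
    n_denominators = n_denominators or {}
    report: dict[str, dict] = {}
    for crit in criteria:
        if crit.observed is None:
            raise ValueError(f"criterion {crit.name!r} has no observed value")
        if crit.observed >= crit.green_limit:
            zone = "green"
        elif crit.observed <= crit.red_limit:
            zone = "red"
        else:
            zone = "amber"
        entry = {
            "observed": crit.observed,
            "red_limit": crit.red_limit,
            "green_limit": crit.green_limit,
            "unit": crit.unit,
            "zone": zone,
        }
        if crit.name in n_denominators:
            n = int(n_denominators[crit.name])
            k = int(round(crit.observed * n))
            entry["n"] = n
            entry["k"] = k
            entry["p_vs_red"] = float(stats.binom.sf(k - 1, n, crit.red_limit))
        report[crit.name] = entry
    return report


def participant_cci(cohort: pd.DataFrame) -> pd.Series:
    """CCI per participant from the serialized complication grade lists."""
    return cohort["complications"].map(
        lambda s: comprehensive_complication_index(parse_grade_list(s))
    )


def median_split_cci_ratio(
    cohort: pd.DataFrame,
    n_boot: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Exploratory median-split analysis of morbidity by achieved weight loss.

    Splits the whole cohort at the median percentage weight loss; the
    estimate is the ratio of mean CCI in the high-loss group (loss at or
    above the median) over the low-loss group, with a percentile bootstrap
    CI (resampling within groups).  ``relative_reduction = 1 - ratio``.
    """
    if rng is None:
        rng = np.random.default_rng()
    loss = -cohort["pct_weight_change"].to_numpy(dtype=float)
    cci = participant_cci(cohort).to_numpy(dtype=float)
    cut = float(np.median(loss))
    high, low = cci[loss >= cut], cci[loss < cut]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("median split produced an empty group")
    if low.mean() == 0.0:
        raise ZeroDivisionError("mean CCI in the reference (low-loss) group is zero; ratio undefined")
    ratio = high.mean() / low.mean()
    boots = np.empty(n_boot)
    for b in range(n_boot):
        h = high[rng.integers(0, len(high), len(high))]
        l = low[rng.integers(0, len(low), len(low))]
        boots[b] = h.mean() / l.mean() if l.mean() > 0 else np.nan
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, ratio), max(hi, ratio)
    est = EffectEstimate(estimate=ratio, ci_low=float(lo), ci_high=float(hi),
                         scale="ratio", n_used=len(cohort))
    return {
        "median_loss_pct": cut,
        "ratio": est,
        "relative_reduction": 1.0 - ratio,
        "n_high_loss": int(len(high)),
        "n_low_loss": int(len(low)),
    }


def itt_set(cohort: pd.DataFrame, outcome: str = "weight_change_surgery") -> pd.DataFrame:
    """Intention-to-treat set: all randomized participants with an observed
    outcome, analyzed in their assigned arm."""
    return cohort[cohort[outcome].notna()]


def per_protocol_set(cohort: pd.DataFrame, outcome: str = "weight_change_surgery") -> pd.DataFrame:
    """Per-protocol set: the whole usual-care arm plus intervention
    participants who achieved the 5 % adherence threshold."""
    observed = itt_set(cohort, outcome)
    adherent = observed["pct_weight_change"].map(classify_adherence) == "adherent"
    keep = (observed["arm"] == "usual_care") | ((observed["arm"] == "intervention") & adherent)
    return observed[keep]


def adherence_table(cohort: pd.DataFrame) -> TwoByTwoTable:
    """2x2 table of adherence (>=5 % loss) by arm, intervention as exposed."""
    cls = cohort["pct_weight_change"].map(classify_adherence)
    is_adh = cls == "adherent"
    is_int = cohort["arm"] == "intervention"
    return TwoByTwoTable(
        a=int((is_int & is_adh).sum()),
        b=int((is_int & ~is_adh).sum()),
        c=int((~is_int & is_adh).sum()),
        d=int((~is_int & ~is_adh).sum()),
    )
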