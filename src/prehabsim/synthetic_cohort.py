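"""Synthetic cohorts for a two-arm preoperative weight-loss feasibility trial.

The generator emulates the data structure of a small randomized trial of an
intensive preoperative total-diet-replacement (TDR) program in adults with
excess weight awaiting colorectal cancer resection: baseline covariates
(age, sex, BMI, WHO performance status), surgical pathway times, weight
trajectories to surgery and 30 days postoperatively, fat-free-mass change,
Clavien-Dindo-graded complications, and retention.

Key structural choices
----------------------
* Pathway times (multidisciplinary-team meeting to randomization,
  randomization to surgery) are right-skewed; they are modeled as lognormal
  distributions fitted to a stated median and IQR, with the
  randomization-to-surgery window truncated below at the trial's minimum
  eligible window (20 days).
* Intervention weight loss accrues with time on the program, but at a
  decelerating rate: the percentage of baseline weight lost by surgery is
  ``rate * median_window * (days / median_window) ** time_exponent`` with a
  participant-specific rate drawn from a normal distribution truncated at
  zero.  ``time_exponent`` < 1 captures the front-loaded trajectory of
  very-low-energy diets and keeps the loss-versus-days correlation moderate.
* The rate distribution is calibrated numerically (:func:`calibrate_loss_rate`)
  so that, at the median window, the proportions achieving >=5 % loss
  (adherent) and <2 % loss (nonadherent) match their targets.
* Usual-care participants drift by a normal weight change around a small
  mean loss, independent of the window length.
* Complication presence is Bernoulli per arm on the logit scale with an
  optional weight-loss effect; affected participants receive a
  zero-truncated Poisson number of events with grades drawn from a
  categorical distribution over Clavien-Dindo grades.

Arms are allocated by the :mod:`prehabsim.randomizer` minimization scheme
(performance status and age stratum, 20 % random element), with quotas so
the final split honors the configured allocation ratio exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .complication_scoring import GRADES, format_grade_list
from .randomizer import MinimizationState, assign_arm

__all__ = [
    "LognormalParams",
    "GeneratorConfig",
    "fit_lognormal_median_iqr",
    "calibrate_loss_rate",
    "simulate_weight_changes",
    "simulate_complications",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "save_config",
    "load_generator_config",
]

ARMS = ("intervention", "usual_care")

#: Cohort-table column order (one row per participant).
COHORT_COLUMNS = [
    "id",
    "arm",
    "age",
    "age_stratum",
    "sex",
    "performance_status",
    "bmi",
    "height",
    "baseline_weight",
    "days_mdt_to_rand",
    "days_rand_to_surgery",
    "weight_change_surgery",
    "weight_change_30d",
    "pct_weight_change",
    "fat_free_mass_change",
    "complications",
    "retained_30d",
]

_Z75 = float(stats.norm.ppf(0.75))


class LognormalParams(NamedTuple):
    """Parameters of a lognormal on the log scale; ``sigma == 0`` is the
    degenerate point mass at ``exp(mu)``."""

    mu: float
    sigma: float

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def ppf(self, q):
        if self.sigma == 0.0:
            return np.full_like(np.asarray(q, dtype=float), self.median)
        return stats.lognorm.ppf(q, s=self.sigma, scale=self.median)

    def cdf(self, x):
        if self.sigma == 0.0:
            return (np.asarray(x, dtype=float) >= self.median).astype(float)
        return stats.lognorm.cdf(x, s=self.sigma, scale=self.median)


def fit_lognormal_median_iqr(median: float, iqr: float) -> LognormalParams:
    """Lognormal parameters whose implied median and IQR match the inputs.

    The median of a lognormal is ``exp(mu)`` and its IQR is
    ``2 exp(mu) sinh(sigma z_75)``, so the fit is closed-form:
    ``mu = log(median)`` and ``sigma = asinh(iqr / (2 median)) / z_75``.
    ``iqr = 0`` gives the degenerate distribution concentrated at the median.
    """
    if not math.isfinite(median) or median <= 0:
        raise ValueError(f"median must be positive, got {median}")
    if not math.isfinite(iqr) or iqr < 0:
        raise ValueError(f"iqr must be nonnegative, got {iqr}")
    sigma = math.asinh(iqr / (2.0 * median)) / _Z75 if iqr > 0 else 0.0
    return LognormalParams(mu=math.log(median), sigma=sigma)


def calibrate_loss_rate(
    p_adherent: float = 0.61,
    p_nonadherent: float = 0.08,
    window_days: float = 33.0,
    adherent_threshold: float = 5.0,
    nonadherent_threshold: float = 2.0,
) -> tuple[float, float]:
    """Solve for the (mean, sd) of the per-day percentage loss rate.

    Finds the zero-truncated normal rate distribution such that, at a fixed
    window of ``window_days``, the proportion losing at least
    ``adherent_threshold`` percent of baseline weight is ``p_adherent`` and
    the proportion losing less than ``nonadherent_threshold`` percent is
    ``p_nonadherent``.  Returns ``(rate_mean, rate_sd)`` in percent of
    baseline weight per day.
    """
    if not 0 < p_nonadherent < p_adherent < 1:
        raise ValueError("need 0 < p_nonadherent < p_adherent < 1")

    lo, hi = nonadherent_threshold, adherent_threshold

    def equations(params):
        m, s = params
        s = abs(s)
        a = -m / s
        tn = stats.truncnorm(a, np.inf, loc=m, scale=s)
        return [tn.sf(hi) - p_adherent, tn.cdf(lo) - p_nonadherent]

    # start from the untruncated-normal two-quantile solution
    z_a = stats.norm.ppf(1 - p_adherent)
    z_n = stats.norm.ppf(p_nonadherent)
    s0 = (hi - lo) / (z_a - z_n)
    m0 = hi - z_a * s0
    sol, info, ier, msg = optimize.fsolve(equations, [m0, s0], full_output=True)
    if ier != 1:
        raise RuntimeError(f"rate calibration did not converge: {msg}")
    m, s = float(sol[0]), float(abs(sol[1]))
    return m / window_days, s / window_days


# Defaults calibrated once via calibrate_loss_rate(0.61, 0.08, 33):
# mixture of adherent (>=5 % loss) and nonadherent (<2 % loss) fractions
# at the 33-day median randomization-to-surgery window.
_DEFAULT_RATE_MEAN, _DEFAULT_RATE_SD = 0.1726981, 0.0891041


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Defaults reproduce the reference feasibility-trial conditions: n = 71
    split 1:1 (the odd participant to the intervention arm), age 64 (8.7)
    years, BMI 35.4 (5.4), 61 % male, 30 % with restricted performance
    status, pathway medians (IQRs) of 17 (27.5) and 33 (17.5) days, ~2 kg
    usual-care drift, a loss-rate mixture giving 61 % adherent / 8 %
    nonadherent at the median window, ~39-40 % of participants with at
    least one mostly minor complication, and 100 % retention.
    """

    n_total: int = 71
    allocation_ratio: tuple[int, int] = (1, 1)
    # baseline covariates
    age_mean: float = 64.0
    age_sd: float = 8.7
    bmi_mean: float = 35.4
    bmi_sd: float = 5.4
    prop_male: float = 0.61
    prop_ps_restricted: float = 0.30
    height_mean_male: float = 1.75
    height_mean_female: float = 1.62
    height_sd: float = 0.07
    # pathway times (days)
    mdt_to_rand_median: float = 17.0
    mdt_to_rand_iqr: float = 27.5
    rand_to_surgery_median: float = 33.0
    rand_to_surgery_iqr: float = 17.5
    min_window: float = 20.0
    # weight dynamics
    control_drift_mean: float = -2.0
    control_drift_sd: float = 2.5
    intervention_rate_mean: float = _DEFAULT_RATE_MEAN  # % of baseline weight / day
    intervention_rate_sd: float = _DEFAULT_RATE_SD
    time_exponent: float = 0.5
    weight_noise_sd: float = 0.5
    postop_drift_mean: float = -2.0
    postop_drift_sd: float = 1.0
    # fat-free mass
    ffm_loss_fraction: dict = field(
        default_factory=lambda: {"intervention": 0.0, "usual_care": 0.05}
    )
    ffm_noise_sd: float = 2.0
    # complications
    p_complication_by_arm: dict = field(
        default_factory=lambda: {"intervention": 0.39, "usual_care": 0.40}
    )
    grade_probs: dict = field(
        default_factory=lambda: {"I": 0.35, "II": 0.45, "IIIa": 0.15, "IIIb": 0.05}
    )
    mean_events_per_affected: float = 51.0 / 28.0
    complication_weightloss_effect: float = 0.0  # log-odds per % of weight lost
    # retention / allocation
    retention_prob: float = 1.0
    random_element: float = 0.2
    seed: Optional[int] = None

    def validation_errors(self) -> list[str]:
        """Every violated invariant, as human-readable messages."""
        errs: list[str] = []
        if self.n_total < 2:
            errs.append(f"n_total must be >= 2, got {self.n_total}")
        if len(self.allocation_ratio) != 2 or any(int(r) <= 0 for r in self.allocation_ratio):
            errs.append(f"allocation_ratio must be a pair of positive integers, got {self.allocation_ratio}")
        for name in (
            "prop_male",
            "prop_ps_restricted",
            "retention_prob",
            "random_element",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must be in [0, 1], got {v}")
        for name in ("age_sd", "bmi_sd", "height_sd", "control_drift_sd",
                     "intervention_rate_sd", "weight_noise_sd", "postop_drift_sd",
                     "ffm_noise_sd"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be nonnegative")
        for name in ("mdt_to_rand_median", "rand_to_surgery_median"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be positive")
        for name in ("mdt_to_rand_iqr", "rand_to_surgery_iqr"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be nonnegative")
        if self.rand_to_surgery_median < self.min_window:
            errs.append(
                f"rand_to_surgery_median ({self.rand_to_surgery_median}) must be >= "
                f"min_window ({self.min_window})"
            )
        if self.intervention_rate_mean < 0:
            errs.append("intervention_rate_mean must be nonnegative")
        if self.time_exponent <= 0:
            errs.append("time_exponent must be positive")
        if set(self.p_complication_by_arm) != set(ARMS):
            errs.append(f"p_complication_by_arm must have keys {ARMS}")
        else:
            for arm, p in self.p_complication_by_arm.items():
                if not 0.0 <= p <= 1.0:
                    errs.append(f"p_complication_by_arm[{arm!r}] must be in [0, 1], got {p}")
        if set(self.ffm_loss_fraction) != set(ARMS):
            errs.append(f"ffm_loss_fraction must have keys {ARMS}")
        bad = set(self.grade_probs) - set(GRADES)
        if bad:
            errs.append(f"grade_probs has unknown grades {sorted(bad)}")
        elif self.grade_probs:
            total = sum(self.grade_probs.values())
            if abs(total - 1.0) > 1e-9:
                errs.append(f"grade_probs must sum to 1, got {total}")
            if any(p < 0 for p in self.grade_probs.values()):
                errs.append("grade_probs must be nonnegative")
        else:
            errs.append("grade_probs must not be empty")
        if self.mean_events_per_affected < 1.0:
            errs.append(
                "mean_events_per_affected must be >= 1 (events are zero-truncated), "
                f"got {self.mean_events_per_affected}"
            )
        return errs

    def __post_init__(self) -> None:
        self.allocation_ratio = tuple(int(r) for r in self.allocation_ratio)
        errs = self.validation_errors()
        if errs:
            raise ValueError("invalid GeneratorConfig:\n  - " + "\n  - ".join(errs))

    def arm_targets(self, n: Optional[int] = None) -> dict[str, int]:
        """Exact arm quotas for ``n`` participants; the remainder after the
        proportional split goes to the intervention arm."""
        n = self.n_total if n is None else n
        r1, r2 = self.allocation_ratio
        n_int = int(math.ceil(n * r1 / (r1 + r2)))
        return {"intervention": n_int, "usual_care": n - n_int}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allocation_ratio"] = list(self.allocation_ratio)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "allocation_ratio" in d:
            d["allocation_ratio"] = tuple(d["allocation_ratio"])
        return cls(**d)

    def content_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws; ``sd == 0`` degenerates to the mean exactly."""
    if sd == 0.0:
        return np.full(size, float(mean))
    return rng.normal(mean, sd, size)


def _truncated_lognormal(
    rng: np.random.Generator, params: LognormalParams, lower: float, size: int
) -> np.ndarray:
    """Inverse-CDF sampling of a lognormal truncated below at ``lower``."""
    if params.sigma == 0.0:
        if params.median < lower:
            raise ValueError("degenerate pathway distribution lies entirely below the truncation bound")
        return np.full(size, params.median)
    f_lo = float(params.cdf(lower)) if lower > 0 else 0.0
    if f_lo >= 1.0:
        raise ValueError("truncation bound leaves no probability mass")
    u = f_lo + (1.0 - f_lo) * rng.random(size)
    return np.asarray(params.ppf(u), dtype=float)


def _truncated_normal_at_zero(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    if sd == 0.0:
        if mean < 0:
            raise ValueError("degenerate rate must be nonnegative")
        return np.full(size, float(mean))
    f_lo = stats.norm.cdf(0.0, loc=mean, scale=sd)
    u = f_lo + (1.0 - f_lo) * rng.random(size)
    return stats.norm.ppf(u, loc=mean, scale=sd)


def simulate_weight_changes(
    cohort: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill the weight-trajectory columns of a cohort with arms and days set.

    Usual care: ``weight_change_surgery ~ N(control_drift_mean, control_drift_sd)``,
    independent of the surgical window.  Intervention: percentage loss
    ``rate * T_med * (days / T_med) ** gamma`` (zero at ``days = 0``) converted
    to kilograms of baseline weight, plus measurement noise.  Both arms share
    a common postoperative drift so the 30-day change preserves the
    between-group difference, and fat-free-mass change is the configured
    fraction of the loss plus noise.
    """
    cohort = cohort.copy()
    n = len(cohort)
    is_int = (cohort["arm"] == "intervention").to_numpy()
    days = cohort["days_rand_to_surgery"].to_numpy(dtype=float)
    weight = cohort["baseline_weight"].to_numpy(dtype=float)

    rates = _truncated_normal_at_zero(
        rng, config.intervention_rate_mean, config.intervention_rate_sd, n
    )
    t_med = config.rand_to_surgery_median
    with np.errstate(invalid="ignore"):
        pct_loss = rates * t_med * np.power(np.maximum(days, 0.0) / t_med, config.time_exponent)
    noise = _normal(rng, 0.0, config.weight_noise_sd, n)
    change_int = -pct_loss / 100.0 * weight + noise
    change_ctrl = _normal(rng, config.control_drift_mean, config.control_drift_sd, n)
    change = np.where(is_int, change_int, change_ctrl)

    postop = _normal(rng, config.postop_drift_mean, config.postop_drift_sd, n)
    ffm_frac = np.where(
        is_int,
        config.ffm_loss_fraction["intervention"],
        config.ffm_loss_fraction["usual_care"],
    )
    ffm_noise = _normal(rng, 0.0, config.ffm_noise_sd, n)

    cohort["weight_change_surgery"] = change
    cohort["weight_change_30d"] = change + postop
    cohort["pct_weight_change"] = 100.0 * change / weight
    cohort["fat_free_mass_change"] = ffm_frac * change + ffm_noise
    return cohort


def _ztp_lambda(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``mean``."""
    if mean < 1.0:
        raise ValueError("zero-truncated Poisson mean must be >= 1")
    if mean == 1.0:
        return 0.0
    return optimize.brentq(lambda l: l / (1.0 - math.exp(-l)) - mean, 1e-12, max(10.0, 5 * mean))


def simulate_complications(
    cohort: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill the ``complications`` column (grade-list serialization).

    Presence per participant is Bernoulli with probability
    ``logistic(logit(p_arm) + effect * pct_lost)`` where ``pct_lost`` is the
    positive percentage of baseline weight lost; a negative effect therefore
    lowers complication odds for participants who lost more.  Affected
    participants receive a zero-truncated Poisson number of events with
    grades drawn i.i.d. from ``grade_probs``.
    """
    cohort = cohort.copy()
    n = len(cohort)
    p_arm = cohort["arm"].map(config.p_complication_by_arm).to_numpy(dtype=float)
    effect = config.complication_weightloss_effect
    if effect != 0.0:
        pct_lost = -cohort["pct_weight_change"].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            logit = np.log(p_arm) - np.log1p(-p_arm)
        prob = 1.0 / (1.0 + np.exp(-(logit + effect * pct_lost)))
        prob = np.where(p_arm <= 0.0, 0.0, np.where(p_arm >= 1.0, 1.0, prob))
    else:
        prob = p_arm
    affected = rng.random(n) < prob

    lam = _ztp_lambda(config.mean_events_per_affected)
    grades = list(config.grade_probs.keys())
    gp = np.array([config.grade_probs[g] for g in grades], dtype=float)
    gp = gp / gp.sum()

    serialized = []
    for i in range(n):
        if not affected[i]:
            serialized.append("")
            continue
        if lam == 0.0:
            k = 1
        else:
            # inverse-CDF draw from Poisson conditioned on > 0
            p0 = math.exp(-lam)
            u = p0 + (1.0 - p0) * rng.random()
            k = int(stats.poisson.ppf(u, lam))
            k = max(k, 1)
        evs = rng.choice(len(grades), size=k, p=gp)
        serialized.append(format_grade_list([grades[j] for j in evs]))
    cohort["complications"] = serialized
    return cohort


def _allocate_arms(
    cohort: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.Series:
    """Sequential minimization allocation with exact arm quotas."""
    state = MinimizationState(
        factors={
            "performance_status": ("0", "1-2"),
            "age_stratum": ("<70", ">=70"),
        },
        arms=ARMS,
        random_element=config.random_element,
    )
    targets = config.arm_targets(len(cohort))
    assigned: list[str] = []
    totals = {a: 0 for a in ARMS}
    for _, row in cohort.iterrows():
        levels = {
            "performance_status": str(row["performance_status"]),
            "age_stratum": str(row["age_stratum"]),
        }
        open_arms = [a for a in ARMS if totals[a] < targets[a]]
        if len(open_arms) == 1:
            arm = open_arms[0]
            state.record(levels, arm)
        else:
            arm = assign_arm(state, levels, rng)
        totals[arm] += 1
        assigned.append(arm)
    return pd.Series(assigned, index=cohort.index)


def generate_cohort(config: GeneratorConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate one complete synthetic cohort table.

    ``seed`` overrides ``config.seed``; identical (config, seed) pairs
    produce identical tables.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_total

    male = rng.random(n) < config.prop_male
    age = _normal(rng, config.age_mean, config.age_sd, n)
    ps_restricted = rng.random(n) < config.prop_ps_restricted
    bmi = np.maximum(_normal(rng, config.bmi_mean, config.bmi_sd, n), 15.0)
    height = np.where(
        male,
        _normal(rng, config.height_mean_male, config.height_sd, n),
        _normal(rng, config.height_mean_female, config.height_sd, n),
    )
    weight = bmi * height**2

    mdt_params = fit_lognormal_median_iqr(config.mdt_to_rand_median, config.mdt_to_rand_iqr)
    surg_params = fit_lognormal_median_iqr(
        config.rand_to_surgery_median, config.rand_to_surgery_iqr
    )
    days_mdt = _truncated_lognormal(rng, mdt_params, 0.0, n)
    days_surg = _truncated_lognormal(rng, surg_params, config.min_window, n)

    cohort = pd.DataFrame(
        {
            "id": [f"P{i + 1:03d}" for i in range(n)],
            "age": np.round(age, 1),
            "age_stratum": np.where(age < 70, "<70", ">=70"),
            "sex": np.where(male, "male", "female"),
            "performance_status": np.where(ps_restricted, "1-2", "0"),
            "bmi": np.round(bmi, 1),
            "height": np.round(height, 3),
            "days_mdt_to_rand": np.round(days_mdt, 1),
            "days_rand_to_surgery": np.round(days_surg, 1),
        }
    )
    cohort["baseline_weight"] = np.round(cohort["bmi"] * cohort["height"] ** 2, 1)
    cohort["arm"] = _allocate_arms(cohort, config, rng)

    cohort = simulate_weight_changes(cohort, config, rng)
    cohort = simulate_complications(cohort, config, rng)
    cohort["retained_30d"] = rng.random(n) < config.retention_prob

    for col in ("weight_change_surgery", "weight_change_30d", "pct_weight_change",
                "fat_free_mass_change"):
        cohort[col] = np.round(cohort[col], 4)
    return cohort[COHORT_COLUMNS]


# -- persistence ----------------------------------------------------------


def write_cohort(
    cohort: pd.DataFrame,
    path,
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = None,
) -> None:
    """Write the cohort CSV and an adjacent ``<name>.provenance.json``."""
    path = Path(path)
    cohort.to_csv(path, index=False)
    prov = {"seed": seed if seed is not None else (config.seed if config else None)}
    if config is not None:
        prov["config_hash"] = config.content_hash()
    path.with_suffix(".provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path, dtype={"performance_status": str})
    cohort["complications"] = cohort["complications"].fillna("")
    return cohort


def save_config(config: GeneratorConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_generator_config(path) -> GeneratorConfig:
    with open(path) as fh:
        return GeneratorConfig.from_dict(yaml.safe_load(fh))
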