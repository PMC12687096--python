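"""Hybrid decision-tree + Markov cohort cost-utility model.

The model compares a preoperative intervention against usual care for a
surgical cohort:

* A **decision tree** covers the first 30 days after surgery.  Each arm
  splits into a morbidity and a no-morbidity branch; the intervention arm's
  morbidity probability is the usual-care probability scaled by
  ``1 - relative_risk_reduction``.  Branches carry 30-day costs and QALYs,
  the intervention arm additionally carries the program cost, and each
  branch hands the cohort to a Markov starting state.
* A **Markov cohort model** then propagates state occupancy through yearly
  cycles (default horizon 30) with per-cycle state costs and utility
  weights.  Exactly one state is absorbing death.  Cycle rewards are
  accrued on the occupancy at the start of each cycle, so with states
  {alive, dead}, per-cycle death probability p and utility 1, total
  undiscounted QALYs equal the geometric sum ``(1 - (1-p)^H) / p``.

Costs and outcomes are discounted at annual rates (UK reference-case
default 3.5 %/year), with Markov cycle t receiving weight ``(1+r)^-t`` and
the tree treated as cycle 0 (undiscounted).  On top of the deterministic
model sit the incremental cost-effectiveness ratio (ICER), probabilistic
sensitivity analysis (PSA) with beta/gamma/normal parameter distributions,
the cost-effectiveness acceptability curve (CEAC), and one-way (tornado)
sensitivity analysis.

Model structure is configuration-driven (YAML via :func:`load_econ_model`);
nothing about the state set is hard-coded.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DecisionTreeSpec",
    "MarkovSpec",
    "MarkovTrace",
    "CostUtilityModel",
    "PSASampleSet",
    "evaluate_decision_tree",
    "run_markov_cohort",
    "discounted_totals",
    "compute_icer",
    "run_psa",
    "compute_ceac",
    "one_way_sensitivity",
    "beta_params_from_mean_sd",
    "gamma_params_from_mean_sd",
    "default_wtp_grid",
    "load_econ_model",
    "plot_ceac",
    "plot_tornado",
]

ARMS = ("intervention", "usual_care")
_ROW_TOL = 1e-9


@dataclass
class DecisionTreeSpec:
    """30-day postoperative decision tree for one pairwise comparison."""

    p_morbidity_usual: float
    branch_costs: dict  # branch -> currency
    branch_qalys: dict  # branch -> QALYs over the tree period
    branch_to_state: dict  # branch -> Markov state label
    relative_risk_reduction: float = 0.20
    intervention_cost: float = 0.0
    branches: tuple[str, str] = ("morbidity", "no_morbidity")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_morbidity_usual <= 1.0:
            raise ValueError(f"p_morbidity_usual must be in [0, 1], got {self.p_morbidity_usual}")
        for m in (self.branch_costs, self.branch_qalys, self.branch_to_state):
            missing = set(self.branches) - set(m)
            if missing:
                raise ValueError(f"branch map missing entries for {sorted(missing)}")


@dataclass
class MarkovSpec:
    """Markov cohort model: states, per-cycle transitions, rewards, horizon.

    ``transition`` is a row-stochastic (S, S) matrix, or (horizon, S, S)
    for cycle-indexed transitions.  The ``death_state`` row must be the
    identity (absorbing).
    """

    states: Sequence[str]
    transition: np.ndarray
    state_costs: Mapping[str, float]
    state_utilities: Mapping[str, float]
    death_state: str = "dead"
    horizon: int = 30
    cycle_length_years: float = 1.0
    discount_costs: float = 0.035
    discount_outcomes: float = 0.035
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        s = len(self.states)
        if len(set(self.states)) != s:
            raise ValueError("state labels must be unique")
        if self.death_state not in self.states:
            raise ValueError(f"death state {self.death_state!r} not among states {self.states}")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        if self.discount_costs < 0 or self.discount_outcomes < 0:
            raise ValueError("discount rates must be nonnegative")
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape == (s, s):
            mats = self.transition[None, :, :]
        elif self.transition.shape == (self.horizon, s, s):
            mats = self.transition
        else:
            raise ValueError(
                f"transition must have shape ({s}, {s}) or ({self.horizon}, {s}, {s}), "
                f"got {self.transition.shape}"
            )
        di = self.states.index(self.death_state)
        for t, mat in enumerate(mats):
            if (mat < -_ROW_TOL).any():
                raise ValueError(f"negative transition probability in cycle-{t} matrix")
            rows = mat.sum(axis=1)
            if np.abs(rows - 1.0).max() > _ROW_TOL:
                raise ValueError(
                    f"transition rows must sum to 1 within {_ROW_TOL}; cycle-{t} row sums {rows}"
                )
            expected = np.zeros(s)
            expected[di] = 1.0
            if np.abs(mat[di] - expected).max() > _ROW_TOL:
                raise ValueError("death row must be the identity (absorbing state)")
        missing_c = set(self.states) - set(self.state_costs)
        missing_u = set(self.states) - set(self.state_utilities)
        if missing_c or missing_u:
            raise ValueError(f"rewards missing for states {sorted(missing_c | missing_u)}")
        for st in self.states:
            if not -1.0 <= self.state_utilities[st] <= 1.0:
                raise ValueError(f"utility for {st!r} must be in [-1, 1]")

    def matrix_at(self, cycle: int) -> np.ndarray:
        if self.transition.ndim == 3:
            return self.transition[cycle]
        return self.transition

    def cost_vector(self) -> np.ndarray:
        return np.array([self.state_costs[s] for s in self.states], dtype=float)

    def utility_vector(self) -> np.ndarray:
        return np.array([self.state_utilities[s] for s in self.states], dtype=float)


class MarkovTrace(NamedTuple):
    """Occupancy per cycle plus undiscounted per-cycle costs and QALYs."""

    states: tuple[str, ...]
    occupancy: np.ndarray  # (horizon + 1, S); row 0 is the initial distribution
    cycle_costs: np.ndarray  # (horizon,)
    cycle_qalys: np.ndarray  # (horizon,)


def evaluate_decision_tree(
    spec: DecisionTreeSpec, arm: str
) -> tuple[float, float, dict[str, float]]:
    """Expected 30-day cost and QALYs for one arm, plus the Markov entry
    distribution implied by the branch probabilities."""
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    p_morb = spec.p_morbidity_usual
    if arm == "intervention":
        p_morb = spec.p_morbidity_usual * (1.0 - spec.relative_risk_reduction)
    if not 0.0 <= p_morb <= 1.0:
        raise ValueError(f"adjusted morbidity probability {p_morb} outside [0, 1]")
    probs = {"morbidity": p_morb, "no_morbidity": 1.0 - p_morb}
    cost = sum(probs[b] * spec.branch_costs[b] for b in spec.branches)
    qaly = sum(probs[b] * spec.branch_qalys[b] for b in spec.branches)
    if arm == "intervention":
        cost += spec.intervention_cost
    init: dict[str, float] = {}
    for b in spec.branches:
        init[spec.branch_to_state[b]] = init.get(spec.branch_to_state[b], 0.0) + probs[b]
    return cost, qaly, init


def run_markov_cohort(spec: MarkovSpec, initial: Mapping[str, float]) -> MarkovTrace:
    """Propagate a cohort through the Markov model.

    ``initial`` maps state labels to the starting occupancy (must sum to 1).
    Cycle t's rewards use the occupancy at the start of cycle t (after t
    transitions) or, with half-cycle correction, the average of start and
    end occupancies.
    """
    s = len(spec.states)
    occ0 = np.zeros(s)
    for state, p in initial.items():
        if state not in spec.states:
            raise ValueError(f"initial distribution names unknown state {state!r}")
        occ0[spec.states.index(state)] = p
    if abs(occ0.sum() - 1.0) > 1e-9 or (occ0 < 0).any():
        raise ValueError("initial distribution must be nonnegative and sum to 1")

    occupancy = np.empty((spec.horizon + 1, s))
    occupancy[0] = occ0
    for t in range(spec.horizon):
        occupancy[t + 1] = occupancy[t] @ spec.matrix_at(t)
    basis = (
        0.5 * (occupancy[:-1] + occupancy[1:]) if spec.half_cycle_correction else occupancy[:-1]
    )
    cycle_costs = basis @ spec.cost_vector()
    cycle_qalys = (basis @ spec.utility_vector()) * spec.cycle_length_years
    return MarkovTrace(
        states=tuple(spec.states),
        occupancy=occupancy,
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
    )


def discounted_totals(per_cycle_values: Sequence[float], rate: float) -> float:
    """Present value of a per-cycle stream; cycle t is weighted
    ``(1 + rate)^-t`` with t starting at 0."""
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    values = np.asarray(per_cycle_values, dtype=float)
    t = np.arange(len(values))
    return float(np.sum(values / (1.0 + rate) ** t))


def compute_icer(cost_int: float, qaly_int: float, cost_uc: float, qaly_uc: float):
    """ICER = incremental cost / incremental QALYs, or a dominance label.

    Returns ``"dominant"`` when the intervention saves money and gains
    QALYs, ``"dominated"`` when it costs more and loses QALYs, and
    ``"undefined"`` when the QALY increment is exactly zero.
    """
    dc = cost_int - cost_uc
    dq = qaly_int - qaly_uc
    if dq == 0.0:
        return "undefined"
    if dc < 0.0 and dq > 0.0:
        return "dominant"
    if dc > 0.0 and dq < 0.0:
        return "dominated"
    return dc / dq


class ArmResult(NamedTuple):
    cost: float
    qalys: float


@dataclass
class CostUtilityModel:
    """The full hybrid model: decision tree feeding the Markov component."""

    tree: DecisionTreeSpec
    markov: MarkovSpec

    def evaluate_arm(self, arm: str) -> ArmResult:
        tree_cost, tree_qaly, init = evaluate_decision_tree(self.tree, arm)
        trace = run_markov_cohort(self.markov, init)
        cost = tree_cost + discounted_totals(trace.cycle_costs, self.markov.discount_costs)
        qalys = tree_qaly + discounted_totals(trace.cycle_qalys, self.markov.discount_outcomes)
        return ArmResult(cost=cost, qalys=qalys)

    def incremental(self) -> tuple[float, float]:
        """(incremental cost, incremental QALYs) of intervention vs usual care."""
        res_i = self.evaluate_arm("intervention")
        res_u = self.evaluate_arm("usual_care")
        return res_i.cost - res_u.cost, res_i.qalys - res_u.qalys

    def icer(self):
        dc, dq = self.incremental()
        return compute_icer(dc, dq, 0.0, 0.0)

    # -- parameter access for PSA / one-way sensitivity -------------------

    def with_params(self, updates: Mapping[str, float]) -> "CostUtilityModel":
        """Copy of the model with dotted-path parameters replaced.

        Supported paths: ``tree.<field>``, ``tree.branch_costs.<branch>``,
        ``tree.branch_qalys.<branch>``, ``markov.state_costs.<state>``,
        ``markov.state_utilities.<state>``, and
        ``markov.transition.<from>.<to>`` (the from-state's diagonal entry
        absorbs the change so the row still sums to 1).
        """
        tree = copy.deepcopy(self.tree)
        markov = copy.deepcopy(self.markov)
        transition = np.array(markov.transition, dtype=float)
        for path, value in updates.items():
            parts = path.split(".")
            if parts[0] == "tree":
                if len(parts) == 2:
                    if not hasattr(tree, parts[1]):
                        raise KeyError(f"unknown tree parameter {path!r}")
                    setattr(tree, parts[1], float(value))
                elif len(parts) == 3 and parts[1] in ("branch_costs", "branch_qalys"):
                    getattr(tree, parts[1])[parts[2]] = float(value)
                else:
                    raise KeyError(f"unknown parameter path {path!r}")
            elif parts[0] == "markov":
                if len(parts) == 3 and parts[1] in ("state_costs", "state_utilities"):
                    if parts[2] not in markov.states:
                        raise KeyError(f"unknown state in path {path!r}")
                    rewards = dict(getattr(markov, parts[1]))
                    rewards[parts[2]] = float(value)
                    setattr(markov, parts[1], rewards)
                elif len(parts) == 4 and parts[1] == "transition":
                    if transition.ndim != 2:
                        raise KeyError("cycle-indexed transitions cannot be varied by path")
                    i = markov.states.index(parts[2])
                    j = markov.states.index(parts[3])
                    delta = float(value) - transition[i, j]
                    transition[i, j] = float(value)
                    transition[i, i] -= delta
                    if transition[i, i] < -_ROW_TOL or transition[i, j] < -_ROW_TOL:
                        raise ValueError(f"varying {path!r} to {value} breaks row-stochasticity")
                else:
                    raise KeyError(f"unknown parameter path {path!r}")
            else:
                raise KeyError(f"unknown parameter path {path!r}")
        markov = MarkovSpec(
            states=markov.states,
            transition=transition,
            state_costs=markov.state_costs,
            state_utilities=markov.state_utilities,
            death_state=markov.death_state,
            horizon=markov.horizon,
            cycle_length_years=markov.cycle_length_years,
            discount_costs=markov.discount_costs,
            discount_outcomes=markov.discount_outcomes,
            half_cycle_correction=markov.half_cycle_correction,
        )
        # re-validate the tree via a fresh construction
        tree = DecisionTreeSpec(
            p_morbidity_usual=tree.p_morbidity_usual,
            branch_costs=tree.branch_costs,
            branch_qalys=tree.branch_qalys,
            branch_to_state=tree.branch_to_state,
            relative_risk_reduction=tree.relative_risk_reduction,
            intervention_cost=tree.intervention_cost,
            branches=tree.branches,
        )
        return CostUtilityModel(tree=tree, markov=markov)


# -- probabilistic sensitivity analysis -----------------------------------


def beta_params_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (alpha, beta) for a beta distribution."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    if sd <= 0 or sd * sd >= mean * (1.0 - mean):
        raise ValueError(f"beta sd {sd} incompatible with mean {mean}")
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_params_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (shape, scale) for a gamma distribution."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma mean and sd must be positive")
    shape = (mean / sd) ** 2
    return shape, mean / shape


def _draw(family: str, spec: Mapping, size: int, rng: np.random.Generator) -> np.ndarray:
    if family == "fixed":
        return np.full(size, float(spec["value"]))
    mean, sd = float(spec["mean"]), float(spec["sd"])
    if sd == 0.0:
        return np.full(size, mean)
    if family == "beta":
        a, b = beta_params_from_mean_sd(mean, sd)
        return rng.beta(a, b, size)
    if family == "gamma":
        shape, scale = gamma_params_from_mean_sd(mean, sd)
        return rng.gamma(shape, scale, size)
    if family == "normal":
        return rng.normal(mean, sd, size)
    if family == "lognormal":
        # moment-matched on the natural scale
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2.0
        return rng.lognormal(mu, np.sqrt(s2), size)
    raise ValueError(f"unknown distribution family {family!r}")


@dataclass
class PSASampleSet:
    """Paired incremental cost/QALY draws with the parameter draws behind them."""

    samples: pd.DataFrame  # columns incremental_cost, incremental_qaly
    parameter_draws: pd.DataFrame
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.parameter_draws):
            raise ValueError("samples and parameter_draws must have equal length")


def run_psa(
    model: CostUtilityModel,
    distributions: Mapping[str, Mapping],
    n_samples: int,
    seed: Optional[int] = None,
) -> PSASampleSet:
    """Probabilistic sensitivity analysis with shared draws across arms.

    ``distributions`` maps parameter paths (see
    :meth:`CostUtilityModel.with_params`) to distribution specs such as
    ``{"family": "beta", "mean": 0.4, "sd": 0.05}``; families are ``beta``,
    ``gamma``, ``normal``, ``lognormal`` and ``fixed``.  Each of the
    ``n_samples`` evaluations applies one joint parameter draw to both arms.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    paths = sorted(distributions)
    draws = {
        p: _draw(distributions[p].get("family", "fixed"), distributions[p], n_samples, rng)
        for p in paths
    }
    dcs = np.empty(n_samples)
    dqs = np.empty(n_samples)
    for k in range(n_samples):
        mk = model.with_params({p: draws[p][k] for p in paths})
        dcs[k], dqs[k] = mk.incremental()
    return PSASampleSet(
        samples=pd.DataFrame({"incremental_cost": dcs, "incremental_qaly": dqs}),
        parameter_draws=pd.DataFrame(draws),
        seed=seed,
    )


def default_wtp_grid() -> np.ndarray:
    """0 to 50 000 per QALY in steps of 500 (the 20 000 threshold included)."""
    return np.arange(0.0, 50_000.0 + 1, 500.0)


def compute_ceac(psa: PSASampleSet, wtp_grid: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Probability of positive net monetary benefit across thresholds.

    At willingness-to-pay lambda the probability cost-effective is the
    fraction of PSA samples with ``lambda * dQ - dC > 0``.
    """
    if len(psa.samples) == 0:
        raise ValueError("PSA sample set is empty")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    dc = psa.samples["incremental_cost"].to_numpy()
    dq = psa.samples["incremental_qaly"].to_numpy()
    prob = [(lam * dq - dc > 0).mean() for lam in grid]
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": prob})


def one_way_sensitivity(
    model: CostUtilityModel, parameter_ranges: Mapping[str, tuple[float, float]]
) -> pd.DataFrame:
    """Tornado table: ICER with each parameter alone at its low/high bound."""
    rows = []
    for path in sorted(parameter_ranges):
        low, high = parameter_ranges[path]
        icer_low = model.with_params({path: low}).icer()
        icer_high = model.with_params({path: high}).icer()
        rows.append({"parameter": path, "low": low, "high": high,
                     "icer_low": icer_low, "icer_high": icer_high})
    return pd.DataFrame(rows, columns=["parameter", "low", "high", "icer_low", "icer_high"])


# -- YAML model documents --------------------------------------------------


class EconModelDocument(NamedTuple):
    model: CostUtilityModel
    psa_distributions: dict
    psa_n_samples: int
    one_way_ranges: dict


def load_econ_model(path) -> EconModelDocument:
    """Load a cost-utility model specification from a YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    t = doc["decision_tree"]
    branches = t["branches"]
    tree = DecisionTreeSpec(
        p_morbidity_usual=float(t["p_morbidity_usual"]),
        relative_risk_reduction=float(t.get("relative_risk_reduction", 0.20)),
        intervention_cost=float(t.get("intervention_cost", 0.0)),
        branch_costs={b: float(v["cost"]) for b, v in branches.items()},
        branch_qalys={b: float(v["qaly"]) for b, v in branches.items()},
        branch_to_state={b: str(v["state"]) for b, v in branches.items()},
        branches=tuple(branches),
    )
    m = doc["markov"]
    states = [str(s) for s in m["states"]]
    mat = np.zeros((len(states), len(states)))
    for i, src in enumerate(states):
        row = m["transition"].get(src, {})
        for dst, p in row.items():
            mat[i, states.index(str(dst))] = float(p)
    markov = MarkovSpec(
        states=states,
        transition=mat,
        state_costs={s: float(m["state_costs"][s]) for s in states},
        state_utilities={s: float(m["state_utilities"][s]) for s in states},
        death_state=str(m.get("death_state", "dead")),
        horizon=int(m.get("horizon", 30)),
        cycle_length_years=float(m.get("cycle_length_years", 1.0)),
        discount_costs=float(m.get("discount_costs", 0.035)),
        discount_outcomes=float(m.get("discount_outcomes", 0.035)),
        half_cycle_correction=bool(m.get("half_cycle_correction", False)),
    )
    psa = doc.get("psa", {})
    one_way = {k: tuple(v) for k, v in doc.get("one_way", {}).items()}
    return EconModelDocument(
        model=CostUtilityModel(tree=tree, markov=markov),
        psa_distributions=dict(psa.get("distributions", {})),
        psa_n_samples=int(psa.get("n_samples", 2000)),
        one_way_ranges=one_way,
    )


# -- figures ---------------------------------------------------------------


def plot_ceac(ceac: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["wtp"], ceac["prob_cost_effective"])
    ax.set_xlabel("Willingness to pay (per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tornado(tornado: pd.DataFrame, base_icer: float, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    numeric = tornado[
        tornado["icer_low"].apply(np.isreal) & tornado["icer_high"].apply(np.isreal)
    ].copy()
    numeric["span"] = (numeric["icer_high"] - numeric["icer_low"]).abs()
    numeric = numeric.sort_values("span")
    fig, ax = plt.subplots(figsize=(6, 0.5 * max(len(numeric), 2) + 1.5))
    for i, (_, row) in enumerate(numeric.iterrows()):
        lo, hi = sorted([row["icer_low"], row["icer_high"]])
        ax.barh(i, hi - lo, left=lo, height=0.6)
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(numeric)))
    ax.set_yticklabels(numeric["parameter"])
    ax.set_xlabel("ICER (per QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
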