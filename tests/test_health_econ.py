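"""Decision tree, Markov cohort model, ICER, PSA, CEAC, tornado."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prehabsim.health_econ import (
    CostUtilityModel,
    DecisionTreeSpec,
    MarkovSpec,
    PSASampleSet,
    beta_params_from_mean_sd,
    compute_ceac,
    compute_icer,
    discounted_totals,
    evaluate_decision_tree,
    one_way_sensitivity,
    run_markov_cohort,
    run_psa,
)


def simple_tree(**kw):
    defaults = dict(
        p_morbidity_usual=0.40,
        relative_risk_reduction=0.20,
        intervention_cost=450.0,
        branch_costs={"morbidity": 13500.0, "no_morbidity": 9000.0},
        branch_qalys={"morbidity": 0.040, "no_morbidity": 0.055},
        branch_to_state={"morbidity": "alive", "no_morbidity": "alive"},
    )
    defaults.update(kw)
    return DecisionTreeSpec(**defaults)


def two_state_markov(p_die=0.1, utility=1.0, cost=0.0, horizon=30, **kw):
    return MarkovSpec(
        states=("alive", "dead"),
        transition=np.array([[1 - p_die, p_die], [0.0, 1.0]]),
        state_costs={"alive": cost, "dead": 0.0},
        state_utilities={"alive": utility, "dead": 0.0},
        death_state="dead",
        horizon=horizon,
        discount_costs=kw.pop("discount_costs", 0.0),
        discount_outcomes=kw.pop("discount_outcomes", 0.0),
        **kw,
    )


def random_markov_spec(rng, n_states=4, horizon=12):
    """Random valid spec: dirichlet rows, last state absorbing death."""
    states = tuple(f"s{i}" for i in range(n_states - 1)) + ("dead",)
    mat = rng.dirichlet(np.ones(n_states), size=n_states)
    mat[-1] = np.eye(n_states)[-1]
    return MarkovSpec(
        states=states,
        transition=mat,
        state_costs={s: float(rng.uniform(0, 1000)) for s in states},
        state_utilities={s: float(rng.uniform(0, 1)) for s in states},
        death_state="dead",
        horizon=horizon,
        discount_costs=0.035,
        discount_outcomes=0.035,
    )


class TestDecisionTree:
    def test_relative_risk_reduction_scales_morbidity(self):
        cost, qaly, init = evaluate_decision_tree(simple_tree(), "intervention")
        p = 0.40 * (1 - 0.20)
        assert p == pytest.approx(0.32)
        assert cost == pytest.approx(p * 13500 + (1 - p) * 9000 + 450)
        assert qaly == pytest.approx(p * 0.040 + (1 - p) * 0.055)
        assert sum(init.values()) == pytest.approx(1.0)

    def test_null_effect_leaves_only_program_cost(self):
        tree = simple_tree(relative_risk_reduction=0.0)
        ci, qi, _ = evaluate_decision_tree(tree, "intervention")
        cu, qu, _ = evaluate_decision_tree(tree, "usual_care")
        assert qi == pytest.approx(qu)
        assert ci - cu == pytest.approx(450.0)

    def test_hand_computed_expectation(self):
        tree = simple_tree(
            p_morbidity_usual=0.25, relative_risk_reduction=0.0, intervention_cost=0.0,
            branch_costs={"morbidity": 100.0, "no_morbidity": 10.0},
            branch_qalys={"morbidity": 0.01, "no_morbidity": 0.08},
        )
        cost, qaly, _ = evaluate_decision_tree(tree, "usual_care")
        assert cost == pytest.approx(0.25 * 100 + 0.75 * 10)
        assert qaly == pytest.approx(0.25 * 0.01 + 0.75 * 0.08)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            evaluate_decision_tree(
                simple_tree(relative_risk_reduction=-2.0), "intervention"
            )


class TestMarkov:
    def test_identity_transition_keeps_occupancy_constant(self):
        spec = two_state_markov(p_die=0.0)
        trace = run_markov_cohort(spec, {"alive": 1.0})
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_geometric_closed_form_qalys(self):
        """Two states, 10 %/cycle mortality, utility 1: total undiscounted
        QALYs over 30 cycles equal (1 - 0.9^30) / 0.1."""
        trace = run_markov_cohort(two_state_markov(), {"alive": 1.0})
        expected = (1 - 0.9**30) / 0.1
        assert trace.cycle_qalys.sum() == pytest.approx(expected, abs=1e-9)

    def test_occupancy_conservation_random_specs(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            spec = random_markov_spec(rng)
            init_raw = rng.dirichlet(np.ones(len(spec.states)))
            trace = run_markov_cohort(spec, dict(zip(spec.states, init_raw)))
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_death_occupancy_nondecreasing(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            spec = random_markov_spec(rng)
            trace = run_markov_cohort(spec, {spec.states[0]: 1.0})
            dead = trace.occupancy[:, spec.states.index("dead")]
            assert np.all(np.diff(dead) >= -1e-12)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MarkovSpec(
                states=("a", "dead"),
                transition=np.array([[0.5, 0.4], [0.0, 1.0]]),
                state_costs={"a": 0.0, "dead": 0.0},
                state_utilities={"a": 1.0, "dead": 0.0},
            )

    def test_non_absorbing_death_rejected(self):
        with pytest.raises(ValueError, match="death row"):
            MarkovSpec(
                states=("a", "dead"),
                transition=np.array([[0.9, 0.1], [0.1, 0.9]]),
                state_costs={"a": 0.0, "dead": 0.0},
                state_utilities={"a": 1.0, "dead": 0.0},
            )

    def test_half_cycle_correction_averages_endpoints(self):
        spec = two_state_markov(half_cycle_correction=True, horizon=1)
        trace = run_markov_cohort(spec, {"alive": 1.0})
        assert trace.cycle_qalys[0] == pytest.approx(0.5 * (1.0 + 0.9))


class TestDiscounting:
    def test_zero_rate_is_plain_sum(self):
        assert discounted_totals([1.0, 2.0, 3.0], 0.0) == pytest.approx(6.0)

    def test_single_value_at_cycle_one(self):
        assert discounted_totals([0.0, 7.0], 0.035) == pytest.approx(7.0 / 1.035)

    def test_constant_stream_matches_annuity_closed_form(self):
        r, n, v = 0.035, 30, 100.0
        # sum_{t=0}^{n-1} v (1+r)^-t
        expected = v * (1 - (1 + r) ** -n) / (1 - (1 + r) ** -1)
        assert discounted_totals([v] * n, r) == pytest.approx(expected, rel=1e-12)

    def test_positive_rate_strictly_reduces_positive_stream(self):
        stream = [10.0] * 10
        assert discounted_totals(stream, 0.05) < sum(stream)


class TestICER:
    def test_ratio_arithmetic(self):
        assert compute_icer(1000.0, 0.5, 0.0, 0.0) == pytest.approx(2000.0)

    def test_dominance_labels(self):
        assert compute_icer(-10.0, 0.1, 0.0, 0.0) == "dominant"
        assert compute_icer(10.0, -0.1, 0.0, 0.0) == "dominated"
        assert compute_icer(10.0, 0.0, 0.0, 0.0) == "undefined"


def full_model():
    tree = simple_tree()
    markov = two_state_markov(
        p_die=0.05, utility=0.8, cost=300.0,
        discount_costs=0.035, discount_outcomes=0.035,
    )
    return CostUtilityModel(tree=tree, markov=markov)


class TestPSA:
    def test_degenerate_distributions_equal_deterministic(self):
        model = full_model()
        dists = {
            "tree.p_morbidity_usual": {"family": "fixed", "value": 0.40},
            "tree.intervention_cost": {"family": "fixed", "value": 450.0},
        }
        psa = run_psa(model, dists, n_samples=5, seed=0)
        dc, dq = model.incremental()
        assert np.allclose(psa.samples["incremental_cost"], dc)
        assert np.allclose(psa.samples["incremental_qaly"], dq)

    def test_reproducible_under_fixed_seed(self):
        model = full_model()
        dists = {"tree.p_morbidity_usual": {"family": "beta", "mean": 0.4, "sd": 0.05}}
        a = run_psa(model, dists, n_samples=50, seed=42)
        b = run_psa(model, dists, n_samples=50, seed=42)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_beta_moment_matching(self, rng):
        a, b = beta_params_from_mean_sd(0.40, 0.05)
        draws = rng.beta(a, b, 10_000)
        assert draws.mean() == pytest.approx(0.40, abs=3 * 0.05 / 100)
        assert draws.std() == pytest.approx(0.05, rel=0.05)

    def test_transition_path_keeps_rows_stochastic(self):
        model = full_model()
        varied = model.with_params({"markov.transition.alive.dead": 0.2})
        assert np.allclose(varied.markov.transition.sum(axis=1), 1.0)
        assert varied.markov.transition[0, 1] == pytest.approx(0.2)


class TestCEAC:
    def make_psa(self, dc, dq):
        return PSASampleSet(
            samples=pd.DataFrame({"incremental_cost": dc, "incremental_qaly": dq}),
            parameter_draws=pd.DataFrame(index=range(len(dc))),
        )

    def test_all_positive_nmb_gives_probability_one(self):
        psa = self.make_psa([10.0, 20.0], [0.1, 0.2])
        ceac = compute_ceac(psa, wtp_grid=[1000.0])
        assert ceac["prob_cost_effective"].iloc[0] == 1.0

    def test_zero_threshold_counts_cost_saving_draws(self):
        psa = self.make_psa([-5.0, 5.0, -1.0, 2.0], [0.1] * 4)
        ceac = compute_ceac(psa, wtp_grid=[0.0])
        assert ceac["prob_cost_effective"].iloc[0] == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_monotone_in_threshold_when_qalys_positive(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        psa = self.make_psa(rng.normal(500, 400, n), rng.uniform(0.01, 0.3, n))
        ceac = compute_ceac(psa, wtp_grid=np.linspace(0, 50_000, 21))
        probs = ceac["prob_cost_effective"].to_numpy()
        assert np.all(np.diff(probs) >= 0)

    def test_limit_at_infinity_is_positive_qaly_fraction(self):
        rng = np.random.default_rng(3)
        dq = rng.normal(0.0, 0.1, 500)
        psa = self.make_psa(rng.normal(0, 100, 500), dq)
        ceac = compute_ceac(psa, wtp_grid=[1e12])
        assert ceac["prob_cost_effective"].iloc[0] == pytest.approx((dq > 0).mean(), abs=0.01)

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError):
            compute_ceac(self.make_psa([], []))


class TestOneWaySensitivity:
    def test_collapsed_range_reproduces_base_icer(self):
        model = full_model()
        base = model.icer()
        tornado = one_way_sensitivity(
            model, {"tree.intervention_cost": (450.0, 450.0)}
        )
        assert tornado["icer_low"].iloc[0] == pytest.approx(base)
        assert tornado["icer_high"].iloc[0] == pytest.approx(base)

    def test_entries_match_direct_re_evaluation(self):
        model = full_model()
        ranges = {
            "tree.intervention_cost": (250.0, 900.0),
            "tree.p_morbidity_usual": (0.30, 0.50),
        }
        tornado = one_way_sensitivity(model, ranges).set_index("parameter")
        for path, (lo, hi) in ranges.items():
            assert tornado.loc[path, "icer_low"] == pytest.approx(
                model.with_params({path: lo}).icer()
            )
            assert tornado.loc[path, "icer_high"] == pytest.approx(
                model.with_params({path: hi}).icer()
            )

    def test_wider_cost_range_widens_icer_span(self):
        # ranges chosen so the intervention stays cost-incurring (numeric ICERs)
        model = full_model()
        narrow = one_way_sensitivity(model, {"tree.intervention_cost": (430.0, 470.0)})
        wide = one_way_sensitivity(model, {"tree.intervention_cost": (400.0, 900.0)})
        span = lambda df: abs(df["icer_high"].iloc[0] - df["icer_low"].iloc[0])
        assert span(wide) >= span(narrow)
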