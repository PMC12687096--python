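"""Synthetic cohort generator: distribution fits, calibration, determinism."""

import io

import numpy as np
import pytest
from scipy import optimize, stats

from prehabsim.synthetic_cohort import (
    GeneratorConfig,
    calibrate_loss_rate,
    fit_lognormal_median_iqr,
    generate_cohort,
    read_cohort,
    simulate_complications,
    simulate_weight_changes,
    write_cohort,
)


class TestLognormalFit:
    @pytest.mark.parametrize("median,iqr", [(33.0, 17.5), (17.0, 27.5), (5.0, 1.0)])
    def test_median_and_iqr_recovered(self, median, iqr):
        params = fit_lognormal_median_iqr(median, iqr)
        dist = stats.lognorm(s=params.sigma, scale=np.exp(params.mu))
        assert dist.median() == pytest.approx(median, abs=1e-6)
        assert dist.ppf(0.75) - dist.ppf(0.25) == pytest.approx(iqr, abs=1e-6)

    def test_sigma_matches_root_finding_oracle(self):
        # independent oracle: solve the IQR equation for sigma numerically
        median, iqr = 17.0, 27.5

        def iqr_of(sigma):
            d = stats.lognorm(s=sigma, scale=median)
            return d.ppf(0.75) - d.ppf(0.25) - iqr

        sigma_oracle = optimize.brentq(iqr_of, 1e-9, 10.0)
        params = fit_lognormal_median_iqr(median, iqr)
        assert params.sigma == pytest.approx(sigma_oracle, abs=1e-9)

    def test_zero_iqr_degenerates_to_point_mass(self):
        params = fit_lognormal_median_iqr(12.0, 0.0)
        assert params.sigma == 0.0
        assert params.median == pytest.approx(12.0)
        assert np.all(params.ppf([0.1, 0.5, 0.9]) == 12.0)

    @pytest.mark.parametrize("median", [0.0, -3.0])
    def test_nonpositive_median_rejected(self, median):
        with pytest.raises(ValueError):
            fit_lognormal_median_iqr(median, 5.0)


class TestRateCalibration:
    def test_mixture_reproduced_by_monte_carlo_oracle(self):
        """The calibrated rate distribution yields the adherence mixture at
        the median surgical window."""
        mean, sd = calibrate_loss_rate(0.61, 0.08, window_days=33.0)
        a = -mean / sd
        rates = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=400_000,
                                    random_state=np.random.default_rng(5))
        pct = rates * 33.0
        assert (pct >= 5.0).mean() == pytest.approx(0.61, abs=0.01)
        assert (pct < 2.0).mean() == pytest.approx(0.08, abs=0.01)

    def test_defaults_match_fresh_calibration(self):
        cfg = GeneratorConfig()
        mean, sd = calibrate_loss_rate(0.61, 0.08, window_days=cfg.rand_to_surgery_median)
        assert cfg.intervention_rate_mean == pytest.approx(mean, rel=1e-4)
        assert cfg.intervention_rate_sd == pytest.approx(sd, rel=1e-4)


class TestWeightChanges:
    def test_zero_exposure_time_gives_zero_intervention_change(self, rng):
        cfg = GeneratorConfig(weight_noise_sd=0.0)
        cohort = generate_cohort(cfg, 1).copy()
        cohort["days_rand_to_surgery"] = 0.0
        filled = simulate_weight_changes(cohort, cfg, rng)
        assert np.allclose(
            filled.loc[filled["arm"] == "intervention", "weight_change_surgery"], 0.0
        )

    def test_degenerate_control_drift_is_exact(self, rng):
        cfg = GeneratorConfig(control_drift_mean=-2.0, control_drift_sd=0.0)
        cohort = generate_cohort(cfg, 2)
        filled = simulate_weight_changes(cohort, cfg, rng)
        ctrl = filled.loc[filled["arm"] == "usual_care", "weight_change_surgery"]
        assert np.allclose(ctrl, -2.0)

    def test_loss_days_correlation_near_reported(self):
        """Intervention weight loss correlates with the surgical window at
        roughly the observed strength (0.38 +/- 0.1)."""
        cohort = generate_cohort(GeneratorConfig(n_total=2000), 3)
        mask = cohort["arm"] == "intervention"
        r = np.corrcoef(
            -cohort.loc[mask, "weight_change_surgery"],
            cohort.loc[mask, "days_rand_to_surgery"],
        )[0, 1]
        assert r == pytest.approx(0.38, abs=0.1)

    def test_thirty_day_change_preserves_group_difference(self):
        cohort = generate_cohort(GeneratorConfig(n_total=2000), 4)
        by_arm = cohort.groupby("arm")[["weight_change_surgery", "weight_change_30d"]].mean()
        diff_surg = by_arm.loc["intervention", "weight_change_surgery"] - \
            by_arm.loc["usual_care", "weight_change_surgery"]
        diff_30 = by_arm.loc["intervention", "weight_change_30d"] - \
            by_arm.loc["usual_care", "weight_change_30d"]
        assert diff_30 == pytest.approx(diff_surg, abs=0.2)


class TestComplications:
    @pytest.mark.parametrize("p,expect_any", [(0.0, False), (1.0, True)])
    def test_degenerate_probabilities(self, p, expect_any, rng):
        cfg = GeneratorConfig(p_complication_by_arm={"intervention": p, "usual_care": p})
        cohort = generate_cohort(cfg, 5)
        filled = simulate_complications(cohort, cfg, rng)
        has_events = (filled["complications"] != "").to_numpy()
        assert has_events.all() if expect_any else not has_events.any()

    def test_affected_fraction_matches_arm_probabilities(self):
        cohort = generate_cohort(GeneratorConfig(n_total=4000), 6)
        frac = cohort.assign(aff=cohort["complications"] != "").groupby("arm")["aff"].mean()
        assert frac["intervention"] == pytest.approx(0.39, abs=0.03)
        assert frac["usual_care"] == pytest.approx(0.40, abs=0.03)

    def test_no_grade_four_or_five_by_default(self, default_cohort):
        joined = ";".join(default_cohort["complications"])
        assert "IV" not in joined and ";V" not in joined and not joined.startswith("V")


class TestGenerateCohort:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_size_and_allocation_split(self, default_config, seed):
        cohort = generate_cohort(default_config, seed)
        assert len(cohort) == 71
        counts = cohort["arm"].value_counts()
        assert counts["intervention"] == 36 and counts["usual_care"] == 35

    def test_identical_seed_gives_identical_table(self, default_config):
        a = generate_cohort(default_config, 7)
        b = generate_cohort(default_config, 7)
        buf_a, buf_b = io.StringIO(), io.StringIO()
        a.to_csv(buf_a, index=False)
        b.to_csv(buf_b, index=False)
        assert buf_a.getvalue() == buf_b.getvalue()

    def test_all_variances_zero_gives_deterministic_draws(self):
        cfg = GeneratorConfig(
            age_sd=0.0, bmi_sd=0.0, height_sd=0.0, prop_male=1.0,
            prop_ps_restricted=0.0, mdt_to_rand_iqr=0.0, rand_to_surgery_iqr=0.0,
            control_drift_sd=0.0, intervention_rate_sd=0.0, weight_noise_sd=0.0,
            postop_drift_sd=0.0, ffm_noise_sd=0.0,
        )
        cohort = generate_cohort(cfg, 8)
        assert (cohort["age"] == 64.0).all()
        assert (cohort["bmi"] == 35.4).all()
        assert (cohort["days_rand_to_surgery"] == 33.0).all()
        assert (cohort["days_mdt_to_rand"] == 17.0).all()
        ctrl = cohort.loc[cohort["arm"] == "usual_care", "weight_change_surgery"]
        assert np.allclose(ctrl, -2.0)

    def test_pct_and_kg_change_consistent(self, default_cohort):
        expected = 100.0 * default_cohort["weight_change_surgery"] / \
            default_cohort["baseline_weight"]
        assert np.allclose(default_cohort["pct_weight_change"], expected, atol=1e-3)

    def test_full_retention_by_default(self, default_cohort):
        assert default_cohort["retained_30d"].all()

    def test_csv_round_trip(self, default_config, default_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(default_cohort, path, config=default_config, seed=1)
        back = read_cohort(path)
        assert len(back) == len(default_cohort)
        assert (back["complications"] == default_cohort["complications"]).all()
        assert path.with_suffix(".provenance.json").exists()


class TestConfigValidation:
    def test_grade_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(grade_probs={"I": 0.5, "II": 0.4})

    def test_all_violations_reported_together(self):
        with pytest.raises(ValueError) as err:
            GeneratorConfig(n_total=1, prop_male=1.5, retention_prob=-0.1)
        msg = str(err.value)
        assert "n_total" in msg and "prop_male" in msg and "retention_prob" in msg

    def test_window_invariant(self):
        with pytest.raises(ValueError, match="min_window"):
            GeneratorConfig(rand_to_surgery_median=15.0, min_window=20.0)
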