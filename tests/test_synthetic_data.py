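"""The study generator: determinism, noise anatomy, contamination knobs."""

import io
import math

import numpy as np
import pytest
from scipy.stats import norm

import centiledesign as cd


class TestDeterminism:
    def test_same_scenario_same_bytes(self, tmp_path):
        scenario = cd.default_scenario(seed=42, n_sites=2, n_subjects_per_site=40)
        for name in ("a.csv", "b.csv"):
            data, _ = cd.generate_study(scenario)
            cd.write_measurements(data, tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seed_different_data(self):
        a, _ = cd.generate_study(cd.default_scenario(seed=1, n_sites=1, n_subjects_per_site=20))
        b, _ = cd.generate_study(cd.default_scenario(seed=2, n_sites=1, n_subjects_per_site=20))
        assert not a["value"].equals(b["value"])

    def test_scenario_json_round_trip(self):
        sc = cd.default_scenario(seed=9, digit_heaping_strength=0.3, site_shifts_sd=(0.5,))
        again = cd.StudyScenario.from_json(sc.to_json())
        assert again == sc


class TestObservationModel:
    def test_zero_noise_reproduces_truth_exactly(self, truth):
        scenario = cd.default_scenario(
            seed=0,
            n_sites=1,
            n_subjects_per_site=25,
            within_replicate_sd=0.0,
            between_subject_scale=0.0,
        )
        data, _ = cd.generate_study(scenario)
        expected = truth.mean_array(data["ga_days"].to_numpy() / 7.0)
        assert data["value"].to_numpy() == pytest.approx(expected, abs=1e-9)

    def test_site_shift_moves_site_mean(self, truth):
        scenario = cd.default_scenario(
            seed=4, n_sites=2, n_subjects_per_site=400, site_shifts_sd=(1.0,)
        )
        data, bundle = cd.generate_study(scenario)
        z = (
            data["value"].to_numpy()
            - truth.mean_array(data["ga_days"].to_numpy() / 7.0)
        ) / truth.sd_array(data["ga_days"].to_numpy() / 7.0)
        z1 = z[(data["site_id"] == "S01").to_numpy()]
        z2 = z[(data["site_id"] == "S02").to_numpy()]
        assert z1.mean() - z2.mean() == pytest.approx(1.0, abs=0.1)
        assert bundle["site_shifts_sd"] == [1.0, 0.0]

    def test_observer_bias_recovered(self):
        scenario = cd.default_scenario(
            seed=8,
            n_sites=1,
            n_subjects_per_site=600,
            observer_biases=(("A", 0.0), ("B", 3.0)),
            within_replicate_sd=0.5,
        )
        data, _ = cd.generate_study(scenario)
        truth = cd.default_truth()
        resid = data["value"].to_numpy() - truth.mean_array(data["ga_days"].to_numpy() / 7.0)
        means = (
            data.assign(resid=resid).groupby("observer_id")["resid"].mean()
        )
        assert means["B"] - means["A"] == pytest.approx(3.0, abs=0.5)

    def test_heaping_detected_by_digit_preference(self):
        scenario = cd.default_scenario(
            seed=10, n_sites=1, n_subjects_per_site=100, digit_heaping_strength=0.5
        )
        data, _ = cd.generate_study(scenario)
        rep = cd.digit_preference(data["value"].to_numpy(), resolution=1.0)
        assert rep.p_value < 1e-6
        # heaping targets 0 three times as often as 5
        assert rep.counts[0] > rep.counts[5] > max(rep.counts[d] for d in (1, 2, 3, 4, 6, 7, 8, 9))

    def test_no_heaping_leaves_digits_uniform(self):
        scenario = cd.default_scenario(seed=11, n_sites=1, n_subjects_per_site=100)
        data, _ = cd.generate_study(scenario)
        rep = cd.digit_preference(data["value"].to_numpy(), resolution=1.0)
        assert rep.p_value > 0.001

    def test_attrition_leaves_expected_completion_share(self):
        scenario = cd.default_scenario(
            seed=12, n_sites=1, n_subjects_per_site=1000, attrition_rate=0.2
        )
        data, _ = cd.generate_study(scenario)
        visits_per_subject = data.groupby("subject_id")["visit"].nunique()
        complete = (visits_per_subject == scenario.n_visits).mean()
        assert complete == pytest.approx(0.8, abs=0.04)
        # dropouts keep their early visits: every subject retains visit 1
        assert (data.groupby("subject_id")["visit"].min() == 1).all()

    def test_schedule_outside_domain_rejected(self):
        with pytest.raises(cd.DomainError, match="domain"):
            cd.default_scenario(entry_window_weeks=(30.0, 40.0))


class TestDating:
    def test_zero_error_all_compatible(self):
        sc = cd.default_scenario(seed=1, lmp_error_sd_days=0.0)
        table = cd.generate_dating(sc, n=500)
        results = [cd.reconcile_gestational_age(r) for r in cd.dating_records(table)]
        assert all(r.compatible for r in results)
        assert all(r.source is cd.DatingSource.LMP for r in results)

    def test_seven_day_error_failure_share(self):
        # the LMP error is recorded in whole days, so the failure event is
        # |round(N(0, 7))| > 7, i.e. |N(0, 7)| >= 7.5, with probability
        # 2 (1 - Phi(7.5/7)) ~ 0.284 (the continuous-error limit 2 (1 - Phi(1))
        # ~ 0.317 ignores the day rounding)
        sc = cd.default_scenario(seed=2, lmp_error_sd_days=7.0)
        table = cd.generate_dating(sc, n=40_000)
        results = [cd.reconcile_gestational_age(r) for r in cd.dating_records(table)]
        share = np.mean([not r.compatible for r in results])
        expected = 2 * (1 - norm.cdf(7.5 / 7.0))
        assert share == pytest.approx(expected, abs=0.01)

    def test_incompatible_records_fall_back_to_ultrasound(self):
        sc = cd.default_scenario(seed=3, lmp_error_sd_days=10.0)
        table = cd.generate_dating(sc, n=2000)
        for row, rec in zip(table.itertuples(index=False), cd.dating_records(table)):
            res = cd.reconcile_gestational_age(rec)
            if abs(row.ga_lmp_days - row.ga_ultrasound_days) > row.tolerance_days:
                assert res.source is cd.DatingSource.ULTRASOUND
                assert res.ga.days == row.ga_ultrasound_days
            else:
                assert res.source is cd.DatingSource.LMP

    def test_ultrasound_matches_true_ga(self):
        table = cd.generate_dating(cd.default_scenario(seed=4), n=100)
        assert (table["ga_ultrasound_days"] == table["ga_true_days"]).all()
        assert table["ga_true_days"].between(63, 97).all()


class TestPipelineRecovery:
    def test_full_pipeline_recovers_truth_curves(self, truth):
        scenario = cd.default_scenario(seed=20, n_sites=1, n_subjects_per_site=2000)
        data, _ = cd.generate_study(scenario)
        agg = cd.aggregate_replicates(data, cd.AggregationRule.MEDIAN_OF_TRIPLICATE)
        model = cd.fit_growth_curve(agg)
        grid = np.linspace(*model.ga_domain, 40)
        rel_mu = np.abs(model.mean_array(grid) - truth.mean_array(grid)) / truth.mean_array(grid)
        # sigma fitted on aggregated data includes the residual median-of-3
        # replicate noise (~ +2% at the default 2 mm), so compare against
        # the correspondingly widened truth
        widened = np.sqrt(truth.sd_array(grid) ** 2 + 0.449 * scenario.within_replicate_sd ** 2)
        rel_sd = np.abs(model.sd_array(grid) - widened) / widened
        assert rel_mu.max() < 0.02
        assert rel_sd.max() < 0.08

    def test_injected_shift_recovered_by_pooling(self):
        data, _ = cd.generate_study(
            cd.pooling_scenario(seed=30, n_subjects_per_site=500, shifted_site_sd=0.6)
        )
        site_models, pooled, _ = cd.fit_site_and_pooled(data)
        res = cd.standardized_differences(site_models, pooled)
        max_delta = res.per_site.set_index("site_id")["max_abs_delta"]
        # the shifted site sits ~ 0.6 * (1 - 1/8) SD from the pooled curve
        assert max_delta["S01"] == pytest.approx(0.6 * 7 / 8, abs=0.12)
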