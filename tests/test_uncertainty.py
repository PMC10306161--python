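"""Sensitivity analyses and calibration."""

import numpy as np
import pandas as pd
import pytest

from ngsbia import (
    CalibrationSpec,
    CalibrationTarget,
    calibrate,
    calibrate_basecase,
    default_parameters,
    get_value,
    one_way_sa,
    run_analysis,
    run_psa,
    scenario_sweep,
)
from ngsbia.parameters import ParameterError


class TestPsa:
    def test_collapsed_ranges_reproduce_base_case(self, base):
        base.uncertainty = {
            path: (get_value(base, path), get_value(base, path))
            for path in base.uncertainty
        }
        result = run_psa(base, 5, seed=0)
        baseline = run_analysis(base)
        assert np.allclose(result.draws["roi"], baseline["roi_discounted"])
        med, lo, hi = result.summaries["roi"]
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_same_seed_bitwise_reproducible(self, base):
        a = run_psa(base, 20, seed=11)
        b = run_psa(base, 20, seed=11)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        assert a.summaries == b.summaries

    def test_different_seeds_differ(self, base):
        a = run_psa(base, 10, seed=1)
        b = run_psa(base, 10, seed=2)
        assert not a.draws["roi"].equals(b.draws["roi"])

    def test_summaries_match_sorted_percentiles(self, base):
        result = run_psa(base, 50, seed=3)
        x = np.sort(result.draws["roi"].to_numpy())
        med, lo, hi = result.summaries["roi"]
        assert med == pytest.approx(np.percentile(x, 50))
        assert lo == pytest.approx(np.percentile(x, 2.5))
        assert hi == pytest.approx(np.percentile(x, 97.5))
        assert lo <= med <= hi

    def test_too_few_draws_rejected(self, base):
        with pytest.raises(ParameterError):
            run_psa(base, 1, seed=0)


class TestTornado:
    def test_zero_width_range_ranked_last_with_zero_span(self, base):
        base.uncertainty = {
            "money.cost_inhouse_test": (578.0, 908.0),
            "money.cost_sendout_test": (300.0, 300.0),  # collapsed
        }
        result = one_way_sa(base, "roi")
        frame = result.to_frame().set_index("parameter")
        assert frame.loc["money.cost_sendout_test", "span"] == pytest.approx(0.0)
        assert result.entries[-1][0] == "money.cost_sendout_test"

    def test_spans_invariant_to_evaluation_order(self, base):
        base.uncertainty = {
            k: base.uncertainty[k]
            for k in (
                "money.cost_inhouse_test",
                "money.reimb_inhouse_test",
                "money.revenue_hospital_visit",
            )
        }
        first = one_way_sa(base, "roi").to_frame()
        reordered = dict(reversed(list(base.uncertainty.items())))
        base.uncertainty = reordered
        second = one_way_sa(base, "roi").to_frame()
        pd.testing.assert_frame_equal(
            first.sort_values("parameter").reset_index(drop=True),
            second.sort_values("parameter").reset_index(drop=True),
        )

    def test_widening_a_range_weakly_increases_its_span(self, base):
        base.uncertainty = {"money.cost_inhouse_test": (578.0, 908.0)}
        narrow = one_way_sa(base, "roi").entries[0][3]
        base.uncertainty = {"money.cost_inhouse_test": (400.0, 1100.0)}
        wide = one_way_sa(base, "roi").entries[0][3]
        assert wide >= narrow


class TestScenarioSweep:
    def test_base_case_grid_point_reproduces_base_roi(self, calibrated):
        p, _ = calibrated
        table = scenario_sweep(p, "inhouse_pct", [75.0])
        baseline = run_analysis(p)
        assert table.loc[0, "roi"] == pytest.approx(baseline["roi_discounted"])

    def test_rows_ordered_by_setting(self, base):
        table = scenario_sweep(base, "patient_volume", [500, 100, 300])
        assert list(table["setting"]) == [100, 300, 500]

    def test_invalid_grid_rejected(self, base):
        with pytest.raises(ParameterError):
            scenario_sweep(base, "inhouse_pct", [150.0])
        with pytest.raises(ParameterError):
            scenario_sweep(base, "bogus_axis", [1.0])


class TestCalibration:
    def test_second_opinion_closed_form_fit(self, base):
        # linear inversion: 173 lost = 2500 x nontargeted mass x p, so
        # p = 173 / (2500 x 0.775240) = 0.089263
        spec = CalibrationSpec(
            free_parameters=[("gaps.p_second_opinion_sendout", 0.0, 1.0)],
            targets=[CalibrationTarget("patients_lost_current", 173.0)],
        )
        fitted, report = calibrate(base, spec)
        assert fitted.gaps.p_second_opinion_sendout == pytest.approx(0.089263, abs=1e-5)
        # forward consistency: re-running the pipeline reproduces the target
        assert run_analysis(fitted)["patients_lost_current"] == pytest.approx(
            173.0, abs=0.01
        )

    def test_zero_free_parameters_is_identity(self, base):
        spec = CalibrationSpec(
            free_parameters=[],
            targets=[CalibrationTarget("patients_lost_current", 173.0)],
        )
        fitted, report = calibrate(base, spec)
        assert fitted == base
        assert len(report) == 1

    def test_two_targets_exactly_determined(self, base):
        spec = CalibrationSpec(
            free_parameters=[
                ("gaps.p_second_opinion_sendout", 0.0, 1.0),
                ("gaps.p_second_opinion_inhouse", 0.0, 1.0),
            ],
            targets=[
                CalibrationTarget("patients_lost_current", 173.0),
                CalibrationTarget("patients_lost_proposed", 64.0),
            ],
        )
        _, report = calibrate(base, spec)
        assert (report["relative_residual"].abs() < 1e-4).all()

    def test_no_targets_rejected(self):
        with pytest.raises(ParameterError):
            CalibrationSpec(free_parameters=[], targets=[])

    def test_basecase_ladder_reports_all_targets(self, calibrated):
        p, report = calibrated
        assert set(report["target"]) == {
            "testing_cost_current",
            "patients_lost_current",
            "patients_lost_proposed",
            "revenue_current",
        }
        assert (report["relative_residual"].abs() < 1e-6).all()
        assert not report["warning"].any()
        # the shared retest multiplier stays inside its constrained band
        assert 1.0 <= p.money.retest_multiplier <= 1.01

    def test_calibration_is_deterministic(self):
        a, _ = calibrate_basecase(default_parameters())
        b, _ = calibrate_basecase(default_parameters())
        assert a == b
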