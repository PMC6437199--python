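"""Antibody index arithmetic, the seropositivity call and the end-to-end
assay pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytocba as c
from cytocba.errors import (
    CalibrationPrerequisiteError,
    DomainError,
    InsufficientPopulationError,
)


class TestPePositiveFraction:
    def test_two_of_two_hundred_is_one_percent(self):
        data = np.full((200, 5), 100.0)
        data[:, c.CHANNELS.index("PE")] = 10.0
        data[:2, c.CHANNELS.index("PE")] = 99.0
        table = c.EventTable("x", "parental", "none", data)
        mask = c.GateMask(np.ones(200, dtype=bool), stage="population")
        assert c.pe_positive_fraction(table, mask, 50.0) == 1.0

    def test_none_above_is_zero(self):
        table = c.EventTable("x", "parental", "none", np.full((50, 5), 10.0))
        mask = c.GateMask(np.ones(50, dtype=bool), stage="population")
        assert c.pe_positive_fraction(table, mask, 50.0) == 0.0

    def test_agrees_with_bruteforce_count(self):
        rng = np.random.default_rng(0)
        data = rng.lognormal(4, 0.6, (1000, 5))
        table = c.EventTable("x", "parental", "none", data)
        mask = c.GateMask(rng.random(1000) < 0.8, stage="population")
        threshold = 90.0
        expected = 0
        total = 0
        for i in range(1000):  # independent loop oracle
            if mask.mask[i]:
                total += 1
                if data[i, 3] > threshold:
                    expected += 1
        assert c.pe_positive_fraction(table, mask, threshold) == \
            100.0 * expected / total

    def test_empty_population_rejected(self, small_table):
        mask = c.GateMask(np.zeros(3, dtype=bool), stage="population")
        with pytest.raises(InsufficientPopulationError):
            c.pe_positive_fraction(small_table, mask, 1.0)


class TestComputeIndex:
    def test_titin_negative_worked_example(self):
        assert c.compute_index(0.91, 1.61) == 0.57

    def test_titin_positive_worked_example(self):
        assert c.compute_index(93.53, 5.76) == 16.2

    @pytest.mark.parametrize("x", [0.5, 1.0, 7.3, 55.0, 100.0])
    def test_identity_ratio_is_one(self, x):
        assert c.compute_index(x, x) == 1.0

    def test_denominator_floored_at_background(self):
        assert c.compute_index(2.0, 0.0) == 4.0

    def test_raw_value_not_rounded(self):
        raw = c.compute_index(0.91, 1.61, rounded=False)
        assert raw == pytest.approx(0.91 / 1.61)

    @pytest.mark.parametrize("t,p", [(-1, 5), (101, 5), (5, -1), (5, 101)])
    def test_out_of_range_percent_rejected(self, t, p):
        with pytest.raises(DomainError):
            c.compute_index(t, p)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(min_value=0, max_value=100),
           st.floats(min_value=0, max_value=100))
    def test_index_nonnegative_and_bounded(self, t, p):
        raw = c.compute_index(t, p, rounded=False)
        assert 0.0 <= raw <= 200.0  # numerator <= 100, denominator >= 0.5

    def test_report_rounding_convention(self):
        assert c.round_index(9.996) == 10.0
        assert c.round_index(10.04) == 10.0
        assert c.round_index(0.5652) == 0.57
        assert c.round_index(16.238) == 16.2


class TestCall:
    @pytest.mark.parametrize("index,expected", [
        (16.2, "positive"), (0.57, "negative"), (1.0, "negative"),
        (1.0000001, "positive"), (0.0, "negative"),
    ])
    def test_strictly_over_one(self, index, expected):
        assert c.call_seropositive(index) == expected

    def test_negative_index_rejected(self):
        with pytest.raises(DomainError):
            c.call_seropositive(-0.1)


class TestRunAssay:
    def test_saturating_positive_serum(self, positive_result):
        assert positive_result.call == "positive"
        assert positive_result.antibody_index_raw > 1.0
        assert positive_result.pe_pct_transfected > 90.0

    def test_zero_titer_serum_negative(self, negative_result):
        assert negative_result.call == "negative"
        assert 0.5 <= negative_result.antibody_index_raw <= 2.0

    def test_control_run_against_itself_within_background(self, config):
        run = c.simulate_assay(c.SimulationParams(seed=13), "titin", "s")
        self_run = c.AssayRun(
            serum_id="ctl", antigen="titin", dilution=100,
            test_parental=run.control_parental,
            test_transfected=run.control_transfected,
            control_parental=run.control_parental,
            control_transfected=run.control_transfected)
        res = c.run_assay(self_run, config)
        assert res.pe_pct_parental <= 0.5
        assert res.pe_pct_transfected <= 0.5

    def test_missing_control_is_calibration_error(self, config):
        run = c.simulate_assay(c.SimulationParams(seed=1), "titin", "s")
        run.control_transfected = None
        with pytest.raises(CalibrationPrerequisiteError):
            c.run_assay(run, config)

    def test_index_invariant_under_global_pe_rescaling(self, config):
        """Multiplying all PE intensities (tests and controls alike) by a
        constant leaves the percentages, hence the index, unchanged."""
        run = c.simulate_assay(
            c.SimulationParams(seed=17, antibody_titer=10.0), "titin", "s")
        base = c.run_assay(run, config)
        for table in run.samples.values():
            table.intensities[:, c.CHANNELS.index("PE")] *= 7.5
        scaled = c.run_assay(run, config)
        assert scaled.pe_pct_parental == base.pe_pct_parental
        assert scaled.pe_pct_transfected == base.pe_pct_transfected
        assert scaled.antibody_index_raw == base.antibody_index_raw

    def test_same_vs_different_gfp_mode_same_call_close_index(self):
        cfg_diff = c.PipelineConfig.default()
        cfg_same = c.PipelineConfig.default()
        cfg_same.gating.gfp_mode = "same"
        for titer in (0.0, 10.0):
            run_a = c.simulate_assay(
                c.SimulationParams(seed=11, antibody_titer=titer), "titin", "s")
            run_b = c.simulate_assay(
                c.SimulationParams(seed=11, antibody_titer=titer), "titin", "s")
            res_diff = c.run_assay(run_a, cfg_diff)
            res_same = c.run_assay(run_b, cfg_same)
            assert res_same.call == res_diff.call
            assert abs(res_same.antibody_index_raw /
                       res_diff.antibody_index_raw - 1) < 0.10

    def test_provenance_recorded(self, positive_result):
        assert positive_result.thresholds_used.pe_threshold_transfected > \
            positive_result.thresholds_used.pe_threshold_parental
        assert positive_result.n_population_parental > 100
        assert len(positive_result.gating_reports) == 2


class TestRunSeries:
    def test_single_run_summary_equals_its_index(self, config):
        run = c.simulate_assay(
            c.SimulationParams(seed=2, antibody_titer=10.0), "titin", "s")
        results, summary = c.run_series([run], config)
        assert summary.mean_index == results[0].antibody_index_raw
        assert summary.max_min_ratio == 1.0

    def test_mixed_sera_rejected(self, config):
        r1 = c.simulate_assay(c.SimulationParams(seed=1), "titin", "a")
        r2 = c.simulate_assay(c.SimulationParams(seed=1), "titin", "b")
        with pytest.raises(DomainError):
            c.run_series([r1, r2], config)

    def test_empty_series_rejected(self, config):
        with pytest.raises(DomainError):
            c.run_series([], config)

    def test_results_table_columns(self, config):
        run = c.simulate_assay(
            c.SimulationParams(seed=2, antibody_titer=10.0), "titin", "s")
        results, _ = c.run_series([run], config)
        table = c.results_table(results)
        for col in ("serum_id", "antigen", "dilution", "antibody_index",
                    "call", "threshold_pe_threshold_parental"):
            assert col in table.columns
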