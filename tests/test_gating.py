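"""Gating stages against simulator ground truth and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytocba as c
from cytocba.errors import (
    CalibrationError,
    DegenerateGeometryError,
    InsufficientEventsError,
    InsufficientPopulationError,
    ParameterError,
)
from cytocba.gating import order_statistic_threshold


def brute_force_threshold(values, rate):
    """Independent oracle: scan observed values ascending and return the
    smallest one leaving at most floor(rate*n) strictly above."""
    values = np.asarray(values, dtype=float)
    k = int(np.floor(rate * len(values)))
    for t in np.sort(values):
        if np.sum(values > t) <= k:
            return float(t)
    raise AssertionError("unreachable")


class TestOrderStatisticThreshold:
    @pytest.mark.parametrize("n", [10, 57, 200, 999, 1000])
    def test_agrees_with_brute_force(self, n):
        rng = np.random.default_rng(n)
        values = rng.lognormal(4.0, 0.5, n)
        assert order_statistic_threshold(values, 0.005) == \
            brute_force_threshold(values, 0.005)

    def test_exact_count_without_ties(self):
        rng = np.random.default_rng(0)
        values = rng.normal(100, 10, 1000)  # continuous, no ties
        t = order_statistic_threshold(np.abs(values), 0.005)
        assert np.sum(np.abs(values) > t) == 5

    def test_two_thousand_events_ten_above(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(4, 0.5, 2000)
        t = order_statistic_threshold(values, 0.005)
        assert np.sum(values > t) == 10

    def test_ties_at_boundary_stay_below_rate(self):
        values = np.concatenate([np.full(990, 10.0), np.full(10, 99.0)])
        # ties at the would-be threshold: strict inequality keeps count <= k
        t = order_statistic_threshold(values, 0.005)
        assert np.sum(values > t) <= int(0.005 * 1000)

    def test_all_equal_values_leave_none_above(self):
        t = order_statistic_threshold(np.full(500, 7.0), 0.005)
        assert t == 7.0

    def test_small_n_floor(self):
        values = np.arange(10.0)
        t = order_statistic_threshold(values, 0.05)
        assert np.sum(values > t) == 0  # floor(0.5) = 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1e4, allow_nan=False),
                    min_size=1, max_size=300),
           st.floats(min_value=0, max_value=0.1))
    def test_bound_and_minimality_property(self, values, rate):
        values = np.asarray(values)
        k = int(np.floor(rate * len(values)))
        t = order_statistic_threshold(values, rate)
        assert np.sum(values > t) <= k
        assert t == brute_force_threshold(values, rate)


class TestLiveGate:
    def test_debris_removed_live_retained(self, config):
        table, truth = c.simulate_sample(
            c.SimulationParams(seed=1, debris_fraction=0.10),
            "parental", "none")
        mask = c.gate_live(table, config.gating)
        debris = truth.population == "debris"
        live = truth.population == "live"
        assert (~mask.mask[debris]).mean() >= 0.90
        assert mask.mask[live].mean() >= 0.90

    def test_tight_cluster_retention_matches_central_mass(self, config):
        rng = np.random.default_rng(0)
        n = 5000
        xy = np.exp(rng.multivariate_normal([11, 10],
                                            [[0.04, 0.01], [0.01, 0.04]], n))
        rest = rng.lognormal(4, 0.5, (n, 3))
        table = c.EventTable("tight", "parental", "none",
                             np.column_stack([xy, rest]))
        mask = c.gate_live(table, config.gating)
        assert mask.retained_fraction >= 0.88

    def test_identical_coordinates_degenerate(self, config):
        table = c.EventTable("deg", "parental", "none",
                             np.tile([[5e4, 2e4, 50.0, 100.0, 60.0]], (200, 1)))
        with pytest.raises(DegenerateGeometryError):
            c.gate_live(table, config.gating)

    def test_too_few_events_rejected(self, config):
        table = c.EventTable("few", "parental", "none",
                             np.ones((10, 5)) * 1e4)
        with pytest.raises(InsufficientEventsError):
            c.gate_live(table, config.gating)


class TestViableGate:
    def test_dead_cells_excluded(self, config):
        table, truth = c.simulate_sample(
            c.SimulationParams(seed=1, dead_fraction=0.05), "parental", "none")
        live = c.gate_live(table, config.gating)
        viable = c.gate_viable(table, live, config.gating.aad_threshold)
        dead = truth.population == "dead"
        assert (~viable.mask[dead]).mean() >= 0.95

    def test_no_dead_cells_barely_changes_mask(self, config):
        table, _ = c.simulate_sample(
            c.SimulationParams(seed=2, dead_fraction=0.0), "parental", "none")
        live = c.gate_live(table, config.gating)
        viable = c.gate_viable(table, live, config.gating.aad_threshold)
        assert viable.retained_fraction / live.retained_fraction >= 0.99

    def test_max_finite_threshold_is_identity(self, config):
        table, _ = c.simulate_sample(c.SimulationParams(seed=3),
                                     "parental", "none")
        live = c.gate_live(table, config.gating)
        viable = c.gate_viable(table, live, np.finfo(float).max)
        np.testing.assert_array_equal(viable.mask, live.mask)

    def test_requires_live_stage_mask(self, config, small_table):
        bad = c.GateMask(np.ones(3, dtype=bool), stage="viable")
        with pytest.raises(ParameterError):
            c.gate_viable(small_table, bad, 1000.0)

    def test_nonfinite_threshold_rejected(self, config, small_table):
        live = c.GateMask(np.ones(3, dtype=bool), stage="live")
        with pytest.raises(ParameterError):
            c.gate_viable(small_table, live, np.inf)


class TestAadCalibration:
    def test_thousand_events_five_above(self):
        rng = np.random.default_rng(0)
        table = c.EventTable("ctl", "parental", "none",
                             np.column_stack([rng.lognormal(11, 0.3, (1000, 2)),
                                              rng.lognormal(4, 0.5, (1000, 3))]))
        t = c.calibrate_aad_threshold(table)
        assert np.sum(table.channel("AAD") > t) == 5

    def test_all_equal_none_above(self):
        data = np.ones((100, 5)) * 50.0
        table = c.EventTable("ctl", "parental", "none", data)
        assert np.sum(table.channel("AAD") >
                      c.calibrate_aad_threshold(table)) == 0

    def test_ten_events_none_above(self):
        rng = np.random.default_rng(1)
        table = c.EventTable("ctl", "parental", "none",
                             rng.lognormal(4, 0.5, (10, 5)))
        t = c.calibrate_aad_threshold(table)
        assert np.sum(table.channel("AAD") > t) == 0


@pytest.fixture(scope="module")
def transfected_control(config):
    table, truth = c.simulate_sample(
        c.SimulationParams(seed=9, transfection_efficiency=0.6),
        "transfected", "titin", None, role="no_serum_with_secondary")
    live = c.gate_live(table, config.gating)
    viable = c.gate_viable(table, live, config.gating.aad_threshold)
    return table, truth, viable


@pytest.fixture(scope="module")
def parental_control(config):
    table, truth = c.simulate_sample(
        c.SimulationParams(seed=10), "parental", "titin", None,
        role="no_serum_with_secondary")
    live = c.gate_live(table, config.gating)
    viable = c.gate_viable(table, live, config.gating.aad_threshold)
    return table, truth, viable


class TestGfpThresholds:
    def test_positive_gate_captures_expressing_cells(
            self, parental_control, transfected_control):
        p_table, _, p_mask = parental_control
        t_table, truth, t_mask = transfected_control
        _, cutoff = c.calibrate_gfp_thresholds(p_table, t_table, "different",
                                               p_mask, t_mask)
        viable = t_mask.mask
        selected = t_table.channel("GFP") > cutoff
        capture = selected[viable & truth.expressing].mean()
        contamination = selected[viable & ~truth.expressing].mean()
        assert capture >= 0.95
        assert contamination <= 0.01

    def test_parental_gate_retains_own_events(self, parental_control):
        table, _, mask = parental_control
        cutoff, _ = c.calibrate_gfp_thresholds(table, table, "same",
                                               mask, mask)
        gfp = table.channel("GFP")[mask.mask]
        assert (gfp < cutoff).mean() >= 0.998

    def test_same_mode_returns_equal_cutoffs(self, parental_control,
                                             transfected_control):
        p_table, _, p_mask = parental_control
        t_table, _, t_mask = transfected_control
        a, b = c.calibrate_gfp_thresholds(p_table, t_table, "same",
                                          p_mask, t_mask)
        assert a == b

    def test_unimodal_transfected_control_is_calibration_error(
            self, parental_control):
        table, _, mask = parental_control  # parental: no expressing mode
        with pytest.raises(CalibrationError, match="unimodal"):
            c.calibrate_gfp_thresholds(table, table, "different", mask, mask)


@pytest.fixture(scope="module")
def gated_transfected(config):
    table, truth = c.simulate_sample(
        c.SimulationParams(seed=12, transfection_efficiency=0.6),
        "transfected", "titin", "s")
    live = c.gate_live(table, config.gating)
    viable = c.gate_viable(table, live, config.gating.aad_threshold)
    return table, truth, viable


class TestSelectPopulation:
    def _thresholds(self, gfp_tr=500.0):
        return c.ThresholdSet(gfp_cutoff_parental=250.0,
                              gfp_cutoff_transfected=gfp_tr,
                              pe_threshold_parental=0.0,
                              pe_threshold_transfected=0.0,
                              aad_threshold=1000.0)

    def test_parental_all_below_cutoff_keeps_viable_mask(self, config):
        table, _ = c.simulate_sample(c.SimulationParams(seed=13),
                                     "parental", "titin", "s")
        live = c.gate_live(table, config.gating)
        viable = c.gate_viable(table, live, config.gating.aad_threshold)
        thresholds = self._thresholds()
        thresholds.gfp_cutoff_parental = table.channel("GFP").max() + 1
        pop = c.select_population(table, thresholds, viable)
        assert pop.retained_fraction == viable.retained_fraction

    def test_transfected_fraction_tracks_efficiency(self, gated_transfected):
        table, truth, viable = gated_transfected
        pop = c.select_population(table, self._thresholds(), viable)
        expected = 0.6 * viable.retained_fraction
        se = np.sqrt(expected * (1 - expected) / table.n_events)
        assert abs(pop.retained_fraction - expected) <= 3 * se

    def test_cutoff_above_all_events_is_insufficient_population(
            self, gated_transfected):
        table, _, viable = gated_transfected
        thresholds = self._thresholds(gfp_tr=table.channel("GFP").max() + 1)
        with pytest.raises(InsufficientPopulationError):
            c.select_population(table, thresholds, viable)

    def test_nesting_population_within_viable_within_live(
            self, config, gated_transfected):
        table, _, viable = gated_transfected
        live = c.gate_live(table, config.gating)
        pop = c.select_population(table, self._thresholds(), viable)
        assert not np.any(pop.mask & ~viable.mask)
        assert not np.any(viable.mask & ~live.mask)


class TestPeBackground:
    def _control(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return c.EventTable("ctl", "parental", "none",
                            rng.lognormal(4, 0.5, (n, 5)))

    def test_two_thousand_events_ten_above(self):
        table = self._control(2000)
        mask = c.GateMask(np.ones(2000, dtype=bool), stage="population")
        t = c.calibrate_pe_background(table, mask)
        assert np.sum(table.channel("PE") > t) == 10

    def test_ties_resolved_by_strict_inequality(self):
        pe = np.concatenate([np.full(995, 10.0), np.full(5, 50.0)])
        data = np.column_stack([np.full((1000, 4), 100.0), pe])[:, [0, 1, 2, 4, 3]]
        table = c.EventTable("ctl", "parental", "none", data)
        mask = c.GateMask(np.ones(1000, dtype=bool), stage="population")
        t = c.calibrate_pe_background(table, mask)
        assert np.mean(table.channel("PE") > t) <= 0.005

    def test_threshold_applied_to_own_control_within_background(self):
        table = self._control(3000, seed=5)
        mask = c.GateMask(np.ones(3000, dtype=bool), stage="population")
        t = c.calibrate_pe_background(table, mask)
        assert c.pe_positive_fraction(table, mask, t) <= 0.5

    def test_empty_population_rejected(self):
        table = self._control(100)
        mask = c.GateMask(np.zeros(100, dtype=bool), stage="population")
        with pytest.raises(CalibrationError):
            c.calibrate_pe_background(table, mask)
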