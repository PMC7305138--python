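import numpy as np
import pytest

from csxrf import (
    DecisionRule,
    PlanError,
    PriorityRule,
    ROIWindow,
    expected_xrf_rate,
    fraction_acquired,
    full_raster_plan,
    log_time,
    mask_from_preview,
    plan_sparse_masked,
    run_combined_scan,
    run_conditional_scan,
    run_dynamic_scan,
    run_full_raster,
    run_plan,
    run_priority_scan,
    time_fraction,
)
from conftest import make_two_phase_phantom


class TestMaskFromPreview:
    @pytest.mark.parametrize(
        "preview, threshold, side, radius, expected",
        [
            (np.full((2, 3), 0.1), 0.5, "below", 0, np.ones((2, 3), bool)),
            (np.array([[0.9, 0.2], [0.2, 0.9]]), 0.5, "below", 0,
             np.array([[False, True], [True, False]])),
            (np.pad([[0.0]], 2, constant_values=1.0), 0.5, "below", 1,
             np.pad([[True] * 3] * 3, 1, constant_values=False)),
        ],
        ids=["saturated", "threshold", "dilated-3x3"],
    )
    def test_threshold_and_dilation(self, preview, threshold, side, radius, expected):
        assert np.array_equal(
            mask_from_preview(np.asarray(preview), threshold, side, radius), expected
        )

    def test_dilation_clipped_at_edges(self):
        preview = np.ones((4, 4))
        preview[0, 0] = 0.0
        mask = mask_from_preview(preview, 0.5, "below", 1)
        assert mask.sum() == 4  # 3x3 block clipped to the corner

    def test_shape_and_side_validation(self):
        with pytest.raises(ValueError):
            mask_from_preview(np.ones(4), 0.5, "below")
        with pytest.raises(ValueError):
            mask_from_preview(np.ones((2, 2)), 0.5, "sideways")


class TestSparsePlanning:
    def test_all_true_mask_is_full_raster(self):
        mask = np.ones((7, 5), bool)
        plan = plan_sparse_masked(mask, 3.0, 1.0, stride=4)
        full = full_raster_plan((7, 5), 3.0)
        assert plan.points == full.points

    def test_stride_sublattice_count(self):
        mask = np.zeros((100, 100), bool)
        plan = plan_sparse_masked(mask, 3.0, 1.0, stride=4, phase=0)
        assert len(plan) == 625
        assert all(r % 4 == 0 and c % 4 == 0 and d == 1.0 for r, c, d in plan.points)

    def test_bernoulli_density_within_binomial_bounds(self):
        # density 0.15 on a megapixel grid: observed count within 5 binomial SD
        mask = np.zeros((1000, 1000), bool)
        plan = plan_sparse_masked(mask, 3.0, 1.0, density=0.15, pattern_seed=3)
        n = 1_000_000
        expected = 0.15 * n
        sd = np.sqrt(n * 0.15 * 0.85)
        assert abs(len(plan) - expected) < 5 * sd

    def test_masked_points_keep_dense_dwell(self):
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        plan = plan_sparse_masked(mask, 2.0, 0.5, stride=3)
        dwells = {(r, c): d for r, c, d in plan.points}
        assert dwells[(2, 2)] == 2.0 and dwells[(0, 0)] == 0.5

    def test_empty_plan_rejected(self):
        with pytest.raises(PlanError):
            plan_sparse_masked(np.zeros((4, 4), bool), 1.0, 1.0, density=1e-9, pattern_seed=0)


class TestRunPlan:
    def test_full_raster_dwell_budget(self, demo):
        log = run_full_raster(demo, 3.0, expected_mode=True)
        assert log.dwell_total == pytest.approx(25 * 3.0)
        assert fraction_acquired(log) == 1.0

    def test_same_plan_and_seed_identical_logs(self, demo):
        plan = full_raster_plan(demo.shape, 0.5)
        a = run_plan(demo, plan, 5)
        b = run_plan(demo, plan, 5)
        assert a.positions() == b.positions()
        assert all(np.array_equal(x.spectrum, y.spectrum) for x, y in zip(a, b))


class TestConditionalScan:
    def test_always_fire_threshold_matches_full_raster_coverage(self, demo):
        rule = DecisionRule("transmission", -np.inf, "above")
        log = run_conditional_scan(demo, rule, 0.02, 3.0, 0, expected_mode=True)
        full = full_raster_plan(demo.shape, 3.0)
        assert log.positions() == [(r, c) for r, c, _ in full.points]

    def test_never_fire_threshold_leaves_stxm_only(self, demo):
        rule = DecisionRule("transmission", np.inf, "above")
        log = run_conditional_scan(demo, rule, 0.02, 3.0, 0)
        assert log.n_points == 0
        assert log_time(log).grand_total == pytest.approx(25 * 0.02)

    def test_time_reduction_from_gated_fraction(self):
        # 34% of pixels absorb (low transmission); XRF dwell is only spent there,
        # so XRF time drops to 34% of the full scan.
        ph = make_two_phase_phantom((50, 50), 850)
        rule = DecisionRule("transmission", 0.5, "below")
        log = run_conditional_scan(ph, rule, 0.02, 3.0, 0, expected_mode=True)
        assert log.n_points == 850
        assert log.dwell_total == pytest.approx(0.34 * 2500 * 3.0)
        assert fraction_acquired(log) == pytest.approx(0.34)

    def test_transmission_recorded_on_acquired_points(self, demo):
        rule = DecisionRule("transmission", 0.8, "below")
        log = run_conditional_scan(demo, rule, 0.02, 1.0, 0)
        assert log.n_points > 0
        for p in log:
            assert p.transmission == demo.transmission[p.row, p.col]

    def test_monotone_in_threshold(self, demo):
        counts = []
        for threshold in (0.0, 0.6, 0.8, 1.1):
            rule = DecisionRule("transmission", threshold, "above")
            counts.append(run_conditional_scan(demo, rule, 0.02, 1.0, 0).n_points)
        assert counts == sorted(counts, reverse=True)


class TestDynamicScan:
    def test_zero_threshold_all_slow(self, demo, demo_rois):
        log = run_dynamic_scan(demo, demo_rois["red"], 0.0, 1.0, 7.0, 0, expected_mode=True)
        assert all(p.dwell == 7.0 for p in log)

    def test_infinite_threshold_all_fast(self, demo, demo_rois):
        log = run_dynamic_scan(demo, demo_rois["red"], np.inf, 1.0, 7.0, 0)
        assert all(p.dwell == 1.0 for p in log)
        assert log.dwell_total == pytest.approx(25 * 1.0)

    def test_each_point_exactly_once(self, demo, demo_rois):
        log = run_dynamic_scan(demo, demo_rois["red"], 5.0, 1.0, 7.0, 0)
        assert sorted(log.positions()) == [(r, c) for r in range(5) for c in range(5)]

    def test_merged_spectrum_equals_rate_times_slow_dwell(self, demo, demo_rois):
        # expected mode: merged fast + top-up record is exactly rate * slow_dwell
        log = run_dynamic_scan(demo, demo_rois["red"], 5.0, 1.0, 7.0, expected_mode=True)
        fired = [p for p in log if p.dwell == 7.0]
        assert fired
        for p in fired:
            np.testing.assert_allclose(
                p.spectrum, expected_xrf_rate(demo, (p.row, p.col)) * 7.0, rtol=1e-12
            )

    def test_two_phase_fixture_reproduces_time_fraction(self):
        # 32% of pixels carry the gating element: the adaptive budget is
        # 0.32*7 + 0.68*1 = 2.92 s/pixel = 41.71% of a full 7 s scan.
        ph = make_two_phase_phantom((10, 10), 32)
        roi = ROIWindow(9, 13)  # Na line at 2.2 keV, gain 0.2
        log = run_dynamic_scan(ph, roi, 50.0, 1.0, 7.0, expected_mode=True)
        slow = sum(p.dwell == 7.0 for p in log)
        assert slow == 32
        from csxrf import raster_time

        frac = time_fraction(log_time(log), raster_time(10, 10, 7.0))
        assert frac == pytest.approx(100 * (0.32 * 7 + 0.68 * 1) / 7)

    def test_fast_must_be_shorter_than_slow(self, demo, demo_rois):
        with pytest.raises(ValueError):
            run_dynamic_scan(demo, demo_rois["red"], 1.0, 7.0, 7.0, 0)


class TestPriorityScan:
    @pytest.fixture
    def demo_rules(self, demo_rois):
        return PriorityRule(
            ((demo_rois["red"], 2.0, 1.2), (demo_rois["blue"], 2.0, 0.6)), 0.2
        )

    def test_dwell_map_matches_regions(self, demo, demo_rules):
        log = run_priority_scan(demo, demo_rules, 0.2, expected_mode=True)
        dwell = np.zeros(demo.shape)
        for p in log:
            dwell[p.row, p.col] = p.dwell
        red = demo.concentration["red"] > 0
        blue = demo.concentration["blue"] > 0
        assert np.all(dwell[red] == 1.2)
        assert np.all(dwell[blue] == 0.6)
        assert np.all(dwell[~red & ~blue] == 0.2)

    def test_empty_rule_list_is_constant_dwell(self, demo):
        log = run_priority_scan(demo, PriorityRule((), 0.4), 0.4, 0)
        assert all(p.dwell == 0.4 for p in log)
        assert log.n_points == 25

    def test_first_match_wins(self, demo, demo_rois):
        # Two rules on the same (red) ROI with increasing thresholds: the
        # first listed rule fires wherever its threshold is met, so the
        # second is unreachable on red pixels.  Verified against brute-force
        # rule evaluation at every pixel of the demo grid.
        rules = PriorityRule(
            ((demo_rois["red"], 1.0, 0.9), (demo_rois["red"], 2.0, 1.5)), 0.2
        )
        log = run_priority_scan(demo, rules, 0.2, expected_mode=True)
        from csxrf import roi_sum

        for p in log:
            probe = expected_xrf_rate(demo, (p.row, p.col)) * 0.2
            expected = 0.2
            for roi, thr, dw in rules.rules:
                if roi_sum(probe, roi) >= thr:
                    expected = dw
                    break
            assert p.dwell == expected

    def test_probe_longer_than_a_rule_dwell_rejected(self, demo, demo_rules):
        with pytest.raises(ValueError):
            run_priority_scan(demo, demo_rules, 0.3, 0)

    def test_merged_dwell_totals(self, demo, demo_rules):
        log = run_priority_scan(demo, demo_rules, 0.2, expected_mode=True)
        assert log.dwell_total == pytest.approx(6 * 1.2 + 5 * 0.6 + 14 * 0.2)


class TestCombinedScan:
    def test_all_true_mask_equals_full_raster(self, demo):
        mask = np.ones(demo.shape, bool)
        rule = DecisionRule("transmission", np.inf, "above")  # irrelevant inside mask
        log = run_combined_scan(demo, mask, rule, 0.02, 3.0, 1.0, 9, stride=2)
        ref = run_plan(demo, full_raster_plan(demo.shape, 3.0), 9)
        assert log.positions() == ref.positions()
        assert all(np.array_equal(a.spectrum, b.spectrum) for a, b in zip(log, ref))

    def test_all_false_mask_with_always_fire_rule_is_sparse_plan(self, demo):
        mask = np.zeros(demo.shape, bool)
        rule = DecisionRule("transmission", -np.inf, "above")
        log = run_combined_scan(demo, mask, rule, 0.02, 3.0, 1.0, 0, stride=2)
        plan = plan_sparse_masked(mask, 3.0, 1.0, stride=2)
        assert log.positions() == [(r, c) for r, c, _ in plan.points]
        assert all(p.dwell == 1.0 for p in log)

    def test_never_fire_rule_keeps_masked_points_only(self):
        ph = make_two_phase_phantom((20, 20), 0)
        mask = np.zeros((20, 20), bool)
        mask[:2, :] = True  # 10% border band
        rule = DecisionRule("transmission", np.inf, "above")
        log = run_combined_scan(ph, mask, rule, 0.02, 3.0, 1.0, 0, stride=10)
        assert set(log.positions()) == {(r, c) for r in range(2) for c in range(20)}
        # STXM charged on every visited point (masked + sparse sublattice)
        visited = int(mask.sum()) + 2 * 2 - int(mask[::10, ::10].sum())
        assert log.stxm_total == pytest.approx(visited * 0.02)
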