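import numpy as np
import pandas as pd
import pytest

import falltiers as ft
from falltiers.engine import decisions_frame


class TestRates:
    @pytest.mark.parametrize(
        "tp,fn,expected",
        [(42, 8, 84.0), (40, 10, 80.0), (44, 6, 88.0), (0, 10, 0.0)],
    )
    def test_sensitivity_from_event_counts(self, tp, fn, expected):
        cm = ft.ConfusionMatrix(tp=tp, fn=fn, fp=0, tn=1)
        assert ft.round_pct(ft.sensitivity(cm)) == expected

    def test_specificity_from_event_counts(self):
        cm = ft.ConfusionMatrix(tp=1, fn=0, fp=2, tn=298)
        assert ft.round_pct(ft.specificity(cm)) == 99.3

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ft.sensitivity(ft.ConfusionMatrix(tp=0, fn=0, fp=1, tn=1))
        with pytest.raises(ValueError):
            ft.specificity(ft.ConfusionMatrix(tp=1, fn=1, fp=0, tn=0))

    def test_weight_group_ratios(self):
        # raw ratios behind the printed per-weight-group rates
        assert ft.sensitivity(ft.ConfusionMatrix(49, 0, 11, 360)) == pytest.approx(100 * 49 / 60)
        assert ft.round_pct(ft.sensitivity(ft.ConfusionMatrix(36, 2, 9, 268))) == 80.0
        assert ft.round_pct(ft.sensitivity(ft.ConfusionMatrix(41, 4, 4, 266))) == 91.1
        assert ft.specificity(ft.ConfusionMatrix(49, 0, 11, 360)) == 100.0
        assert ft.specificity(ft.ConfusionMatrix(36, 2, 9, 268)) == pytest.approx(100 * 268 / 270)
        assert ft.round_pct(ft.specificity(ft.ConfusionMatrix(41, 4, 4, 266))) == 98.5


class TestFMeasure:
    def test_hybrid_event_counts(self):
        assert ft.f_measure(ft.ConfusionMatrix(tp=126, fp=6, fn=24, tn=894)) == pytest.approx(
            252 / 282
        )

    def test_perfect_and_worthless(self):
        assert ft.f_measure(ft.ConfusionMatrix(10, 0, 0, 5)) == 1.0
        assert ft.f_measure(ft.ConfusionMatrix(0, 1, 1, 5)) == 0.0

    def test_undefined_without_positives(self):
        with pytest.raises(ValueError):
            ft.f_measure(ft.ConfusionMatrix(0, 0, 0, 5))


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(77, 99.8, 88.4), (82, 98, 90.0), (86, 99.5, 92.75), (100, 100, 100.0)],
    )
    def test_mean_of_rates(self, sens, spec, expected):
        assert ft.balanced_accuracy(sens, spec) == pytest.approx(expected)

    def test_range_checked(self):
        with pytest.raises(ValueError):
            ft.balanced_accuracy(101, 50)


class TestMcNemar:
    def test_symmetric_disagreement_is_null(self):
        stat, p = ft.mcnemar_test(ft.PairedOutcomes(5, 5))
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_asymmetric_disagreement(self):
        stat, p = ft.mcnemar_test(ft.PairedOutcomes(10, 2))
        assert stat == pytest.approx(64 / 12)
        assert p == pytest.approx(0.0209, abs=2e-4)

    def test_continuity_correction_floor(self):
        stat, _ = ft.mcnemar_test(ft.PairedOutcomes(1, 0), continuity_correction=True)
        assert stat == 0.0

    def test_no_discordance_rejected(self):
        with pytest.raises(ValueError):
            ft.mcnemar_test(ft.PairedOutcomes(0, 0))

    def test_one_sided_halves_the_tail(self):
        stat, p2 = ft.mcnemar_test(ft.PairedOutcomes(10, 2))
        _, p1 = ft.mcnemar_test(ft.PairedOutcomes(10, 2), alternative="greater")
        assert p1 == pytest.approx(p2 / 2)

    def test_asymptotic_agrees_with_exact_binomial(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(25, 80))
            b = int(rng.binomial(n, 0.5))
            c = n - b
            if b == c:
                continue
            _, p_asym = ft.mcnemar_test(ft.PairedOutcomes(b, c), continuity_correction=True)
            p_exact = ft.mcnemar_exact(ft.PairedOutcomes(b, c))
            assert p_asym == pytest.approx(p_exact, abs=0.01)

    def test_from_correctness_counts_discordant_pairs(self):
        a = [True, True, False, True, False]
        b = [True, False, True, True, False]
        pairs = ft.PairedOutcomes.from_correctness(a, b)
        assert (pairs.b, pairs.c) == (1, 1)


class TestEvaluateRun:
    def _decisions(self, outcomes):
        return pd.DataFrame(
            {
                "frame_index": range(len(outcomes)),
                "outcome": outcomes,
            }
        )

    def _manifest(self, rows):
        return pd.DataFrame(rows, columns=["event_id", "kind", "label", "start_frame", "end_frame"])

    def test_perfect_detector(self):
        manifest = self._manifest(
            [(0, "FALL_HARSH", "FALL", 0, 1), (1, "WALK", "NON_FALL", 2, 3)]
        )
        decisions = self._decisions(["FALL", "ELIMINATED_MOTIONLESS", "DAILY_ACTIVITY", "DAILY_ACTIVITY"])
        cm = ft.evaluate_run(decisions, manifest)
        assert cm == ft.ConfusionMatrix(tp=1, fp=0, fn=0, tn=1)

    def test_silent_detector_misses_all_falls(self):
        manifest = self._manifest([(i, "FALL_HARSH", "FALL", i, i) for i in range(4)])
        cm = ft.evaluate_run(self._decisions(["DAILY_ACTIVITY"] * 4), manifest)
        assert (cm.tp, cm.fn) == (0, 4)

    def test_grouping_by_kind(self):
        manifest = self._manifest(
            [(0, "FALL_HARSH", "FALL", 0, 0), (1, "FALL_SLOW", "FALL", 1, 1)]
        )
        by_kind = ft.evaluate_run(self._decisions(["FALL", "DAILY_ACTIVITY"]), manifest, group_by="kind")
        assert by_kind["FALL_HARSH"].tp == 1
        assert by_kind["FALL_SLOW"].fn == 1

    def test_missing_decision_is_an_error(self):
        manifest = self._manifest([(0, "WALK", "NON_FALL", 0, 5)])
        with pytest.raises(ValueError, match="frame"):
            ft.evaluate_run(self._decisions(["DAILY_ACTIVITY"]), manifest)

    def test_rerun_is_deterministic(self, trained_model):
        trace, manifest = ft.generate_benchmark(20, 40, seed=42)
        d1, _, _ = ft.run_pipeline(trace.frames(), model=trained_model)
        d2, _, _ = ft.run_pipeline(trace.frames(), model=trained_model)
        assert ft.evaluate_run(d1, manifest) == ft.evaluate_run(d2, manifest)

    def test_frame_level_false_positive_rate(self, trained_model):
        trace = ft.generate_daily_life(hours=0.2, activity_fraction=0.2, seed=6)
        decisions, _, _ = ft.run_pipeline(trace.frames(), model=trained_model)
        fpr = ft.frame_false_positive_rate(decisions_frame(decisions), trace.frame_labels)
        assert 0.0 <= fpr < 0.05


class TestCalibration:
    def test_single_point_grid_returned(self, small_benchmark):
        trace, manifest = small_benchmark
        cfg = ft.DTConfig()
        table, best = ft.calibrate_thresholds(trace, manifest, [cfg])
        assert len(table) == 1
        assert best == cfg

    def test_deployed_point_separates_harsh_falls_from_walks(self):
        trace, manifest = ft.generate_benchmark(
            20, 20, mix={"FALL_HARSH": 1.0, "WALK": 1.0}, seed=13
        )
        table, _ = ft.calibrate_thresholds(trace, manifest, [ft.DTConfig()])
        assert table.loc[0, "tpr"] == 1.0
        assert table.loc[0, "fpr"] == 0.0

    def test_raising_high_threshold_never_detects_more(self, small_benchmark):
        trace, manifest = small_benchmark
        grid = [ft.DTConfig(th_high=h) for h in (2.0, 2.4, 2.8, 3.2)]
        table, _ = ft.calibrate_thresholds(trace, manifest, grid, mode="exclude")
        assert (np.diff(table["tp"]) <= 0).all()

    def test_empty_grid_rejected(self, small_benchmark):
        trace, manifest = small_benchmark
        with pytest.raises(ValueError):
            ft.calibrate_thresholds(trace, manifest, [])

    def test_choice_minimizes_fpr_then_maximizes_tpr(self):
        trace, manifest = ft.generate_benchmark(
            10, 10, mix={"FALL_HARSH": 1.0, "WALK": 1.0}, seed=21
        )
        # absurdly low th_high detects everything incl. region-II leaks
        grid = [ft.DTConfig(), ft.DTConfig(th_low=1.05, th_high=1.1, th_inactivity=1.0)]
        _, best = ft.calibrate_thresholds(trace, manifest, grid, mode="exclude")
        assert best == ft.DTConfig()
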