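"""Landmark detection, fate calling, exit-probability modelling."""

import numpy as np
import pytest
from scipy import stats

from clockrace.synthetic_data import CellTrace, TreatmentProgram
from clockrace.trace_analysis import (AnalysisConfig, TraceFeatures,
                                      classify_fates, detect_exit,
                                      detect_mitosis, detect_s_entry,
                                      exit_fraction_by_offset,
                                      fit_exit_logistic, order_for_heatmap)

STEP = 0.2


def build_trace(cdk2=None, apc=None, horizon=30.0, divisions=(),
                treatment_time=10.0, label="CDK46I"):
    """Handcrafted trace from per-time callables or constants."""
    t = np.arange(0.0, horizon + STEP / 2, STEP)

    def channel(values, default):
        if values is None:
            return np.full_like(t, default)
        if callable(values):
            return np.array([values(x) for x in t], dtype=float)
        return np.full_like(t, float(values))

    return CellTrace(
        cell_id="t0", times=t,
        cdk2=channel(cdk2, 1.0), apc=channel(apc, 1.0), ccna2=None,
        division_times=list(divisions),
        treatment=TreatmentProgram(label, treatment_time=treatment_time),
        preset_name="MCF10A",
    )


CFG = AnalysisConfig()


class TestDetectSEntry:
    def test_never_inactivated(self):
        assert detect_s_entry(build_trace(apc=1.0), CFG) is None

    def test_step_function(self):
        tr = build_trace(apc=lambda x: 1.0 if x < 5.0 else 0.0)
        assert detect_s_entry(tr, CFG) == pytest.approx(5.0)

    def test_single_frame_blip_rejected(self):
        def apc(x):
            if abs(x - 3.0) < STEP / 2:
                return 0.4
            return 1.0 if x < 6.0 else 0.0
        assert detect_s_entry(build_trace(apc=apc), CFG) == pytest.approx(6.0)

    def test_missing_channel(self):
        tr = build_trace()
        tr.apc = None
        with pytest.raises(ValueError, match="apc"):
            detect_s_entry(tr, CFG)


class TestDetectMitosis:
    def test_event_channel_takes_priority(self):
        tr = build_trace(divisions=[18.2], treatment_time=10.0)
        assert detect_mitosis(tr, CFG) == pytest.approx(18.2)

    def test_event_before_treatment_ignored(self):
        tr = build_trace(divisions=[8.0], treatment_time=10.0)
        assert detect_mitosis(tr, CFG) is None

    def test_cdk2_collapse_detector(self):
        def cdk2(x):
            if x < 20.0:
                return 0.5 + 0.04 * x  # climbs past 1.0
            return 0.3
        tr = build_trace(cdk2=cdk2)
        assert detect_mitosis(tr, CFG) == pytest.approx(20.0)

    def test_monotone_rise_is_not_mitosis(self):
        tr = build_trace(cdk2=lambda x: 0.5 + 0.02 * x)
        assert detect_mitosis(tr, CFG) is None


class TestDetectExit:
    def test_sustained_high_activity(self):
        assert detect_exit(build_trace(cdk2=0.9), CFG) is None

    def test_linear_ramp_interpolated_crossing(self):
        def cdk2(x):
            if x < 10.0:
                return 1.0
            return max(1.0 - 0.2 * (x - 10.0), 0.2)
        tr = build_trace(cdk2=cdk2)
        assert detect_exit(tr, CFG) == pytest.approx(12.0, abs=1e-9)

    def test_default_threshold_is_the_commitment_level(self):
        assert CFG.cdk2_exit_threshold == 0.6

    def test_crossing_at_recording_end_is_censored(self):
        def cdk2(x):
            return 1.0 if x < 29.5 else 0.4
        assert detect_exit(build_trace(cdk2=cdk2), CFG) is None

    def test_post_division_collapse_is_not_exit(self):
        def cdk2(x):
            return 1.2 if x < 20.0 else 0.1
        tr = build_trace(cdk2=cdk2, divisions=[20.0])
        assert detect_exit(tr, CFG) is None
        assert detect_mitosis(tr, CFG) == pytest.approx(20.0)


class TestClassifyFates:
    def test_divider_daughters_arrest(self):
        def cdk2(x):
            return (0.8 + 0.025 * x) if x < 18.0 else 0.12
        def apc(x):
            return 0.05 if 6.0 <= x < 18.0 else 1.0
        tr = build_trace(cdk2=cdk2, apc=apc, divisions=[18.0])
        f = classify_fates([tr], CFG)[0]
        assert f.fate == "MITOSIS"
        assert f.endpoint == "G0_2N"
        assert f.post_r_at_treatment

    def test_exit_to_g0_like_state(self):
        def cdk2(x):
            return 1.1 if x < 10.0 else max(1.1 - 0.05 * (x - 10.0), 0.05)
        def apc(x):
            return 0.05 if 6.0 <= x < 22.0 else 1.0
        tr = build_trace(cdk2=cdk2, apc=apc)
        f = classify_fates([tr], CFG)[0]
        assert f.fate == "EXIT"
        assert f.endpoint == "G0LIKE_4N"
        assert f.exit_time is not None and f.mitosis_time is None

    def test_apc_active_at_treatment_is_pre_r(self):
        tr = build_trace(apc=1.0)
        f = classify_fates([tr], CFG)[0]
        assert f.fate == "PRE_R"
        assert not f.post_r_at_treatment

    def test_fates_partition_post_r_population(self, competition_features):
        post_r = [f for f in competition_features if f.post_r_at_treatment]
        counted = sum(f.fate in ("MITOSIS", "EXIT", "COMMITTED")
                      for f in post_r)
        assert counted == len(post_r)
        assert len(post_r) == len(competition_features)  # all post-R cohort

    def test_mutual_exclusivity(self, competition_features):
        for f in competition_features:
            assert not (f.mitosis_time is not None
                        and f.exit_time is not None)

    def test_landmarks_match_generator_truth(self, mcf10a, analysis_cfg):
        """On noiseless traces the detected landmarks equal the generating
        ones to within one frame (exit: interpolated, much closer)."""
        from clockrace.synthetic_data import generate_population
        traces = generate_population(
            mcf10a, TreatmentProgram("CDK46I_CDK1I"), 60, seed=106,
            noise=False, return_truth=True)
        for tr in traces:
            s = detect_s_entry(tr, analysis_cfg)
            assert abs(s - tr.truth["s_entry"]) <= STEP + 1e-9
            if tr.truth["fate"] == "EXIT":
                e = detect_exit(tr, analysis_cfg)
                if e is not None:  # late exits are right-censored
                    assert abs(e - 12.0 - tr.truth["t_exit"]) <= 0.02


class TestExitFractionByOffset:
    def test_all_exits(self):
        feats = [TraceFeatures(f"c{i}", 5.0, None, 14.0 + i, True,
                               float(i % 5), "EXIT", "G0LIKE_4N")
                 for i in range(10)]
        tab = exit_fraction_by_offset(feats, 1.0)
        nonempty = tab[tab["n"] > 0]
        assert (nonempty["fraction"] == 1.0).all()

    def test_declines_with_offset_on_synthetic_population(
            self, competition_features):
        tab = exit_fraction_by_offset(competition_features, 1.0)
        filled = tab[tab["n"] > 20]
        rho = stats.spearmanr(filled["bin_center"], filled["fraction"])
        assert rho.statistic < -0.8

    def test_empty_input(self):
        assert exit_fraction_by_offset([], 1.0).empty

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            exit_fraction_by_offset([], -1.0)


def _binary_features(offsets, outcomes):
    return [TraceFeatures(f"c{i}", 5.0,
                          None if y else 20.0,
                          18.0 if y else None,
                          True, float(x),
                          "EXIT" if y else "MITOSIS",
                          "G0LIKE_4N" if y else "G0_2N")
            for i, (x, y) in enumerate(zip(offsets, outcomes))]


class TestLogisticFit:
    def test_null_type_one_error(self):
        """With outcomes independent of offset, the Wald test should
        rarely reject at the 5% level."""
        rejections = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            offs = rng.uniform(0, 6, 500)
            ys = rng.random(500) < 0.5
            fit = fit_exit_logistic(_binary_features(offs, ys))
            rejections += (not fit.degenerate) and fit.p_value < 0.05
        assert rejections <= 5

    def test_one_class_outcome_is_degenerate(self):
        offs = np.linspace(0, 6, 50)
        fit = fit_exit_logistic(_binary_features(offs, [False] * 50))
        assert fit.degenerate

    def test_perfect_separation_flagged(self):
        offs = np.linspace(0, 6, 60)
        ys = offs < 3.0
        fit = fit_exit_logistic(_binary_features(offs, ys))
        assert fit.degenerate
        assert np.isinf(fit.slope)

    def test_synthetic_population_has_negative_trend(
            self, competition_features):
        fit = fit_exit_logistic(competition_features)
        assert not fit.degenerate
        assert fit.slope < 0
        assert fit.p_value < 0.01

    def test_requires_two_distinct_offsets(self):
        with pytest.raises(ValueError):
            fit_exit_logistic(_binary_features([2.0, 2.0], [True, False]))


class TestHeatmapOrdering:
    def test_dividers_first_by_mitosis_time(self):
        feats = [
            TraceFeatures("a", 1.0, 12.0, None, True, 2.0, "MITOSIS", "G0_2N"),
            TraceFeatures("b", 1.0, 8.0, None, True, 2.0, "MITOSIS", "G0_2N"),
            TraceFeatures("c", 1.0, None, 20.0, True, 2.0, "EXIT",
                          "G0LIKE_4N"),
        ]
        assert order_for_heatmap(feats) == ["b", "a", "c"]

    def test_non_dividers_by_exit_time(self):
        feats = [
            TraceFeatures("a", 1.0, None, 22.0, True, 2.0, "EXIT", "G0LIKE_4N"),
            TraceFeatures("b", 1.0, None, 15.0, True, 2.0, "EXIT", "G0LIKE_4N"),
        ]
        assert order_for_heatmap(feats) == ["b", "a"]

    def test_stable_for_ties(self):
        feats = [
            TraceFeatures("a", 1.0, 10.0, None, True, 2.0, "MITOSIS", "G0_2N"),
            TraceFeatures("b", 1.0, 10.0, None, True, 2.0, "MITOSIS", "G0_2N"),
        ]
        assert order_for_heatmap(feats) == ["a", "b"]


def test_config_validation():
    with pytest.raises(ValueError):
        AnalysisConfig(cdk2_exit_threshold=2.0)
    with pytest.raises(ValueError):
        AnalysisConfig(mitosis_drop_fraction=0.0)
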