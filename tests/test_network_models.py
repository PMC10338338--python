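"""Feedback vs feed-forward network architectures.

The feedback switch must be bistable and irreversibly ON after mitogen
removal; the feed-forward chain must have a unique steady state (no
hysteresis) but a long transient that mimics irreversibility at the time
a cell would normally enter mitosis.
"""

import numpy as np
import pytest

from clockrace.network_models import (Architecture, MitogenSchedule,
                                      build_network, dose_response,
                                      hysteresis_width, simulate_network,
                                      steady_state)

DOSE_STEP = 0.02  # test-suite dose grid; coarser than the library default


@pytest.fixture(scope="module")
def feedback():
    return build_network(Architecture.FEEDBACK)


@pytest.fixture(scope="module")
def feedforward():
    return build_network(Architecture.FEEDFORWARD)


@pytest.fixture(scope="module")
def ff_removal_traj(feedforward):
    """Feed-forward trajectory after mitogen removal at t = 0 from the
    proliferating steady state."""
    return simulate_network(feedforward, MitogenSchedule.constant(0.0),
                            horizon=200.0, init="HIGH")


class TestBuildNetwork:
    def test_feedforward_has_no_return_edge_to_transcription(self, feedforward):
        """Perturbing CDK2 (or Rb) must leave the mRNA balance untouched."""
        y = np.array([1.0, 0.1, 0.8, 0.9, 0.7, 0.6])
        base = feedforward.rhs(0.0, y, S=1.0)
        for idx in (feedforward.state_names.index("cdk2"),
                    feedforward.state_names.index("rb_phos")):
            bumped = y.copy()
            bumped[idx] += 0.3
            d = feedforward.rhs(0.0, bumped, S=1.0)
            i_m = feedforward.state_names.index("mrna")
            assert d[i_m] == pytest.approx(base[i_m], abs=1e-12)

    def test_feedback_closes_the_cdk2_rb_e2f_loop(self, feedback):
        """Raising CDK2 must increase Rb phosphorylation flux (the loop's
        return edge), which feeds E2F and cyclin synthesis."""
        y = np.array([0.0, 0.5, 0.5, 0.5])
        base = feedback.rhs(0.0, y, S=0.0)
        bumped = y.copy()
        bumped[feedback.state_names.index("cdk2")] += 0.5
        d = feedback.rhs(0.0, bumped, S=0.0)
        i_rp = feedback.state_names.index("rb_phos")
        assert d[i_rp] > base[i_rp]

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError, match="k_nonexistent"):
            build_network(Architecture.FEEDBACK,
                          overrides={"k_nonexistent": 1.0})

    def test_override_applied(self):
        m = build_network(Architecture.FEEDFORWARD,
                          overrides={"protein_half_life": 5.0})
        assert m.params["protein_half_life"] == 5.0


class TestTrajectories:
    def test_feedforward_reaches_zero_after_mitogen_removal(
            self, ff_removal_traj):
        k0 = ff_removal_traj["cdk2"].iloc[0]
        assert ff_removal_traj["cdk2"].iloc[-1] < 1e-3 * k0

    def test_feedforward_still_high_at_mitosis_time(self, ff_removal_traj):
        k0 = ff_removal_traj["cdk2"].iloc[0]
        at11 = ff_removal_traj.loc[
            (ff_removal_traj["time_h"] - 11.0).abs().idxmin(), "cdk2"]
        assert at11 > 0.85 * k0

    def test_feedback_stays_high_after_mitogen_removal(self, feedback):
        traj = simulate_network(feedback, MitogenSchedule.constant(0.0),
                                horizon=200.0, init="HIGH")
        assert traj["cdk2"].iloc[-1] > 0.9 * traj["cdk2"].iloc[0]

    def test_component_ordering_mrna_before_cdk2(self, ff_removal_traj):
        """mRNA is lost on the ~2 h scale while CDK2 activity holds near
        its initial level for over 6 h before declining."""
        m0 = ff_removal_traj["mrna"].iloc[0]
        k0 = ff_removal_traj["cdk2"].iloc[0]
        t_half_m = ff_removal_traj.loc[
            ff_removal_traj["mrna"] <= 0.5 * m0, "time_h"].iloc[0]
        assert 1.5 <= t_half_m <= 3.5
        sustained = ff_removal_traj.loc[
            ff_removal_traj["cdk2"] >= 0.95 * k0, "time_h"].iloc[-1]
        assert sustained >= 6.0

    def test_non_negative_states(self, ff_removal_traj):
        assert (ff_removal_traj.drop(columns="time_h").to_numpy() >= 0).all()

    def test_insensitive_to_tolerance(self, feedforward):
        kw = dict(horizon=50.0, init="HIGH")
        a = simulate_network(feedforward, MitogenSchedule.constant(0.0),
                             rtol=1e-8, atol=1e-10, **kw)
        b = simulate_network(feedforward, MitogenSchedule.constant(0.0),
                             rtol=5e-9, atol=5e-11, **kw)
        scale = max(a["cdk2"].max(), 1e-12)
        assert np.max(np.abs(a["cdk2"] - b["cdk2"])) / scale < 0.01

    def test_invalid_horizon(self, feedforward):
        with pytest.raises(ValueError):
            simulate_network(feedforward, MitogenSchedule.constant(0.0), -1.0)


class TestRescuePerturbations:
    @pytest.mark.parametrize("flag", ["knockout_repressor",
                                      "constitutive_ccna2"])
    def test_perturbation_abolishes_exit(self, feedforward, flag):
        sched = MitogenSchedule.constant(0.0, **{flag: True})
        traj = simulate_network(feedforward, sched, horizon=200.0,
                                init="HIGH")
        assert traj["cdk2"].iloc[-1] > 0.9 * traj["cdk2"].iloc[0]


class TestSteadyStates:
    @pytest.mark.parametrize("S", [0.0, 0.3, 0.7, 1.0])
    def test_feedforward_unique_steady_state(self, feedforward, S):
        hi = steady_state(feedforward, S, "HIGH")
        lo = steady_state(feedforward, S, "LOW")
        assert np.allclose(hi, lo, atol=1e-5)

    def test_feedback_bistable_window(self, feedback):
        hi = steady_state(feedback, 0.2, "HIGH")
        lo = steady_state(feedback, 0.2, "LOW")
        i = feedback.cdk2_index
        assert hi[i] > 1.0 and lo[i] < 0.1

    @pytest.mark.parametrize("arch", ["FEEDBACK", "FEEDFORWARD"])
    def test_full_mitogen_turns_cdk2_on(self, arch):
        model = build_network(arch)
        for init in ("HIGH", "LOW"):
            y = steady_state(model, 1.0, init)
            assert y[model.cdk2_index] > 0.5

    def test_invalid_mitogen_level(self, feedback):
        with pytest.raises(ValueError):
            steady_state(feedback, 1.5, "HIGH")


class TestDoseResponseAndHysteresis:
    def test_feedforward_branches_coincide_at_steady_state(self, feedforward):
        doses = np.linspace(0, 1, 21)
        hi = dose_response(feedforward, doses, None, "HIGH")["cdk2"]
        lo = dose_response(feedforward, doses, None, "LOW")["cdk2"]
        assert np.max(np.abs(hi.to_numpy() - lo.to_numpy())) < 0.02

    def test_feedforward_transient_apparent_irreversibility(self, feedforward):
        """At the time a cell would normally enter mitosis (~11 h) the
        post-R branch is still on at doses where the pre-R branch is off."""
        hi = dose_response(feedforward, [1.0], 11.0, "HIGH")["cdk2"].iloc[0]
        lo = dose_response(feedforward, [1.0], 11.0, "LOW")["cdk2"].iloc[0]
        assert hi > 0.6
        assert lo < 0.1

    def test_feedforward_no_hysteresis_at_steady_state(self, feedforward):
        width = hysteresis_width(feedforward, None, dose_step=DOSE_STEP)
        assert width <= DOSE_STEP

    def test_feedback_hysteresis_at_steady_state(self, feedback):
        width = hysteresis_width(feedback, None, dose_step=DOSE_STEP)
        assert width > 0.1

    def test_feedforward_apparent_hysteresis_at_eleven_hours(self,
                                                             feedforward):
        width = hysteresis_width(feedforward, 11.0, dose_step=DOSE_STEP)
        assert width > 0.1

    def test_invalid_dose(self, feedforward):
        with pytest.raises(ValueError):
            dose_response(feedforward, [1.5], None, "HIGH")


def test_schedule_validation():
    with pytest.raises(ValueError):
        MitogenSchedule(segments=((5.0, 1.0),))  # must start at 0
    with pytest.raises(ValueError):
        MitogenSchedule(segments=((0.0, 2.0),))  # level outside [0, 1]
    with pytest.raises(ValueError):
        MitogenSchedule(segments=((0.0, 1.0), (0.0, 0.5)))  # non-increasing
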