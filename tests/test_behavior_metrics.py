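"""Behavioral metrics on hand-countable trials plus entropy properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popdisorg.behavior_metrics import (
    TransitionMatrix,
    entropy_zscore,
    foraging_metrics,
    preferential_metrics,
    superfluous_saccade_rate,
    transition_entropy,
    transition_matrix,
)
from popdisorg.core_data import FixationEvent, LayoutItem, SaccadeEvent, Trial
from popdisorg.errors import (
    ParameterError,
    SessionExcludedError,
    UndefinedMetricError,
)
from popdisorg.synthetic_data import ForagingSimConfig, simulate_foraging_session

from conftest import make_foraging_trial, make_gap_trial, make_session


class TestSuperfluousRate:
    def test_three_of_ten_trials(self, gap_session):
        assert superfluous_saccade_rate(gap_session) == pytest.approx(0.3)

    def test_saccade_inside_fixation_window_not_counted(self):
        # landing 0.8 deg from the spot stays within the 1.0 deg window
        t = make_gap_trial(0, [SaccadeEvent(600.0, 0.8, 0.0),
                               SaccadeEvent(850.0, 8.0, 0.0)])
        assert superfluous_saccade_rate(make_session([t])) == 0.0

    def test_saccade_outside_gap_not_counted(self):
        t = make_gap_trial(0, [SaccadeEvent(400.0, 5.0, 0.0),  # before offset
                               SaccadeEvent(850.0, 8.0, 0.0)])
        assert superfluous_saccade_rate(make_session([t])) == 0.0

    def test_no_completed_trials_undefined(self):
        t = make_gap_trial(0, [], completed=False)
        with pytest.raises(UndefinedMetricError):
            superfluous_saccade_rate(make_session([t]))


class TestForagingMetrics:
    def test_no_revisits(self):
        t = make_foraging_trial(0, [1, 2, 3], rewarded={0, 1, 2})
        m = foraging_metrics(make_session([t]))
        assert m.revisit_rate == 0.0
        assert m.reward_per_fixation == 1.0

    def test_one_revisit_in_three_visits(self):
        t = make_foraging_trial(0, [1, 2, 1])
        assert foraging_metrics(make_session([t])).revisit_rate == pytest.approx(1 / 3)

    def test_consecutive_duplicates_collapse_for_distance(self):
        layout = [LayoutItem(0, 0.0, 0.0, "target"), LayoutItem(1, 3.0, 4.0, "target")]
        t = make_foraging_trial(0, [0, 1, 1], layout=layout,
                                positions=[(0.0, 0.0), (3.0, 4.0), (3.0, 4.0)])
        m = foraging_metrics(make_session([t]))
        assert m.mean_interfix_distance_deg == pytest.approx(5.0)

    def test_no_on_stimulus_fixations_undefined(self):
        t = make_foraging_trial(0, [-1, -1])
        with pytest.raises(UndefinedMetricError):
            foraging_metrics(make_session([t]))


class TestPreferentialMetrics:
    def _trial(self, segments):
        """segments: list of (cls, duration_ms), cls 0=novel 1=familiar."""
        layout = [LayoutItem(0, 6.0, 0.0, "novel_image"),
                  LayoutItem(1, -6.0, 0.0, "familiar_image")]
        fixations = []
        t = 0.0
        for cls, dur in segments:
            x = 6.0 if cls == 0 else -6.0
            fixations.append(FixationEvent(t, t + dur, x, 0.0, cls))
            t += dur + 20.0
        return Trial(trial_id=0, task="preferential", fixations=fixations,
                     layout=layout, timing={"image_onset": 0.0})

    def test_preference_from_dwell_times(self):
        t = self._trial([(0, 600.0), (1, 400.0)])
        assert preferential_metrics(make_session([t])).novelty_preference == \
            pytest.approx(0.6)

    def test_switch_count(self):
        t = self._trial([(0, 300.0), (1, 300.0), (0, 400.0)])
        assert preferential_metrics(make_session([t])).switches_per_trial == 2.0

    def test_zero_dwell_undefined(self):
        layout = [LayoutItem(0, 6.0, 0.0, "novel_image"),
                  LayoutItem(1, -6.0, 0.0, "familiar_image")]
        t = Trial(trial_id=0, task="preferential",
                  fixations=[FixationEvent(0.0, 100.0, 0.0, 0.0, -1)],
                  layout=layout, timing={"image_onset": 0.0})
        with pytest.raises(UndefinedMetricError):
            preferential_metrics(make_session([t]))


class TestTransitionMatrix:
    def test_deterministic_cycle_rows_are_permutation(self, foraging_session):
        tm = transition_matrix(foraging_session)
        rows = tm.counts.sum(axis=1) > 0
        p = tm.p[rows]
        assert np.all(np.isin(p, [0.0, 1.0]))
        assert transition_entropy(tm) == 0.0

    def test_hand_counted_transitions(self):
        trials = [make_foraging_trial(i, [1, 2, 1, 3]) for i in range(20)]
        tm = transition_matrix(make_session(trials))
        assert tm.counts[1, 2] == 20 and tm.counts[2, 1] == 20
        assert tm.counts[1, 3] == 20 and tm.counts.sum() == 60

    def test_nineteen_completed_trials_excluded(self):
        trials = [make_foraging_trial(i, [0, 1, 2]) for i in range(19)]
        with pytest.raises(SessionExcludedError):
            transition_matrix(make_session(trials))
        trials.append(make_foraging_trial(19, [0, 1, 2]))
        transition_matrix(make_session(trials))  # exactly 20 passes

    def test_elsewhere_breaks_the_chain(self):
        trials = [make_foraging_trial(i, [1, -1, 2, 3]) for i in range(20)]
        tm = transition_matrix(make_session(trials))
        assert tm.counts[1, 2] == 0  # pair bridged by an elsewhere fixation
        assert tm.counts[2, 3] == 20

    def test_single_location_undefined(self):
        trials = [make_foraging_trial(i, [4, 4, 4]) for i in range(20)]
        with pytest.raises(UndefinedMetricError):
            transition_matrix(make_session(trials))


class TestTransitionEntropy:
    def test_single_half_half_row_is_one_bit(self):
        counts = np.zeros((3, 3), dtype=np.int64)
        counts[0, 1] = counts[0, 2] = 5
        tm = TransitionMatrix(p=counts / 10, counts=counts,
                              occupancy=np.array([10, 5, 5]),
                              location_ids=np.arange(3))
        assert transition_entropy(tm) == pytest.approx(1.0)

    def test_row_sum_vs_rate_conventions(self):
        counts = np.zeros((2, 2), dtype=np.int64)
        counts[0, 1] = 3
        counts[1, 0] = 1
        tm = TransitionMatrix(p=np.eye(2)[::-1], counts=counts,
                              occupancy=np.array([3, 1]),
                              location_ids=np.arange(2))
        assert transition_entropy(tm, "row-sum") == 0.0
        assert transition_entropy(tm, "rate") == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 4), min_size=2, max_size=40))
    def test_entropy_nonnegative_and_zero_iff_deterministic(self, seq):
        trials = [make_foraging_trial(0, seq)]
        try:
            tm = transition_matrix(make_session(trials), min_completed=1)
        except UndefinedMetricError:
            return
        h = transition_entropy(tm)
        assert h >= 0.0
        deterministic = all((row > 0).sum() <= 1 for row in tm.counts)
        assert (h == 0.0) == deterministic


class TestEntropyZScore:
    def test_z_invariant_to_location_relabeling(self):
        sess = simulate_foraging_session(ForagingSimConfig(n_trials=20, seed=9))
        z1 = entropy_zscore(sess, n_shuffles=200, seed=0).z
        perm = np.random.default_rng(1).permutation(9)
        for t in sess.trials:
            t.fixations = [type(f)(f.onset, f.offset, f.x, f.y, int(perm[f.location_id]))
                           for f in t.fixations]
        z2 = entropy_zscore(sess, n_shuffles=200, seed=0).z
        assert z1 == pytest.approx(z2, abs=1e-9)

    def test_degenerate_two_visit_session_has_undefined_z(self):
        sess = make_session([make_foraging_trial(0, [1, 2])])
        res = entropy_zscore(sess, n_shuffles=50, seed=0, min_completed=1)
        assert res.sigma_shuffled == 0.0 and np.isnan(res.z) and not res.defined

    def test_null_moments_reported(self):
        sess = simulate_foraging_session(ForagingSimConfig(n_trials=20, seed=3))
        res = entropy_zscore(sess, n_shuffles=100, seed=5)
        assert res.n_shuffles == 100 and res.n_transitions > 0
        assert res.z == pytest.approx((res.H - res.mu_shuffled) / res.sigma_shuffled)

    def test_too_few_shuffles_rejected(self, foraging_session):
        with pytest.raises(ParameterError):
            entropy_zscore(foraging_session, n_shuffles=1)
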