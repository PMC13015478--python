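"""Generator ground-truth contracts: seeding, closed forms, limiting cases."""

import numpy as np
import pytest

from popdisorg.behavior_metrics import (
    preferential_metrics,
    superfluous_saccade_rate,
    transition_matrix,
)
from popdisorg.errors import ParameterError
from popdisorg.synthetic_data import (
    ForagingSimConfig,
    GainModelConfig,
    OUModelConfig,
    TunedPopConfig,
    gain_model_rho,
    simulate_foraging_session,
    simulate_gap_session,
    simulate_longitudinal_study,
    simulate_ou_spike_trains,
    simulate_population_counts,
    simulate_preferential_session,
    simulate_tuned_responses,
)


class TestForaging:
    def test_deterministic_policy_has_one_successor_per_row(self):
        sess = simulate_foraging_session(ForagingSimConfig(structure=1.0, seed=0))
        for t in sess.trials:
            single = transition_matrix(
                type(sess)(session_id="x", day=0, subject_id="m", trials=[t]),
                min_completed=1)
            rows = single.counts.sum(axis=1) > 0
            assert np.all((single.counts[rows] > 0).sum(axis=1) == 1)

    def test_uniform_policy_rows_converge_to_uniform(self):
        # pooled over >= 10,000 transitions each row ~ uniform over the 8 others
        sess = simulate_foraging_session(
            ForagingSimConfig(structure=0.0, n_trials=160,
                              n_fixations_per_trial=10, seed=1))
        tm = transition_matrix(sess)
        assert tm.n_transitions >= 1400
        off_diag = tm.p[~np.eye(9, dtype=bool)].reshape(9, 8)
        # modest sample here; the law-of-large-numbers check at >=10k
        # transitions runs in the acceptance suite
        assert np.abs(off_diag - 1 / 8).max() < 0.08

    def test_seed_reproducibility(self):
        a = simulate_foraging_session(ForagingSimConfig(seed=7))
        b = simulate_foraging_session(ForagingSimConfig(seed=7))
        for ta, tb in zip(a.trials, b.trials):
            assert [f.location_id for f in ta.fixations] == \
                   [f.location_id for f in tb.fixations]

    def test_rewards_first_target_visit_only(self):
        sess = simulate_foraging_session(ForagingSimConfig(structure=1.0, seed=2))
        for t in sess.trials:
            targets = {it.location_id for it in t.layout if it.role == "target"}
            seen = set()
            for i, f in enumerate(t.fixations):
                if f.location_id in targets and f.location_id not in seen:
                    assert i in t.rewarded_fixation_ids
                else:
                    assert i not in t.rewarded_fixation_ids
                seen.add(f.location_id)

    def test_structure_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            ForagingSimConfig(structure=1.5)


class TestGap:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_probabilities_exact(self, p, expected):
        sess = simulate_gap_session(p, n_trials=50, seed=0)
        assert superfluous_saccade_rate(sess) == expected

    def test_rate_estimate_matches_probability(self):
        # binomial SE at p=0.3, n=10,000 is ~0.0046
        sess = simulate_gap_session(0.3, n_trials=10_000, seed=1)
        assert abs(superfluous_saccade_rate(sess) - 0.3) < 0.015

    def test_negative_gap_rejected(self):
        with pytest.raises(ParameterError):
            simulate_gap_session(0.5, gap_ms=-1.0)


class TestPreferential:
    def test_preference_converges(self):
        # per-trial novel fraction has sd ~0.4 (few segments per second);
        # pooled over 2,000 trials the SE is ~0.009
        sess = simulate_preferential_session(0.5, n_trials=2000, seed=0)
        assert abs(preferential_metrics(sess).novelty_preference - 0.5) < 0.027

    def test_zero_switch_rate_means_zero_switches(self):
        sess = simulate_preferential_session(0.6, switch_rate=0.0, n_trials=40, seed=1)
        assert preferential_metrics(sess).switches_per_trial == 0.0

    def test_full_preference_is_exactly_one(self):
        sess = simulate_preferential_session(1.0, n_trials=40, seed=2)
        pm = preferential_metrics(sess)
        assert pm.novelty_preference == 1.0
        assert np.isnan(pm.fixation_duration_ms["familiar"])

    def test_switch_rate_sets_switch_count(self):
        sess = simulate_preferential_session(0.5, switch_rate=3.0, n_trials=400, seed=3)
        pm = preferential_metrics(sess)
        # ~3 switches/s over 1 s viewing, minus boundary truncation
        assert 1.8 < pm.switches_per_trial < 3.5


class TestGainModel:
    def test_closed_form_against_brute_force_oracle(self):
        # independent simulation of the doubly stochastic model, no package code
        rng = np.random.default_rng(0)
        lam_t = np.array([5.0, 5.0])
        s2 = 0.01
        g = rng.gamma(1 / s2, s2, size=400_000)
        n = rng.poisson(np.outer(g, lam_t))
        rho_mc = np.corrcoef(n, rowvar=False)[0, 1]
        rho_cf = gain_model_rho(np.array([25.0, 25.0]), 200.0, s2)[0, 1]
        assert rho_cf == pytest.approx(0.25 / 5.25, abs=1e-12)
        assert rho_mc == pytest.approx(rho_cf, abs=0.005)

    def test_independent_units_uncorrelated(self):
        cm = simulate_population_counts(
            GainModelConfig(n_units=20, n_trials=2000, gain_var=0.0, seed=1))
        c = np.corrcoef(cm.counts, rowvar=False)
        off = c[~np.eye(20, dtype=bool)]
        assert np.abs(off).mean() < 3 / np.sqrt(2000)

    def test_mean_counts_match_rates(self):
        cfg = GainModelConfig(n_units=5, n_trials=4000, rates_hz=[10, 20, 25, 30, 40],
                              gain_var=0.01, seed=2)
        cm = simulate_population_counts(cfg)
        mu = np.asarray(cfg.rates_hz) * 0.2
        se = np.sqrt(mu * (1 + mu * cfg.gain_var) / cfg.n_trials)
        assert np.all(np.abs(cm.counts.mean(axis=0) - mu) < 3.5 * se)

    def test_ground_truth_attached(self):
        cm = simulate_population_counts(GainModelConfig(n_units=3, n_trials=50, seed=0))
        assert cm.meta["rho_true"].shape == (3, 3)


class TestOUModel:
    def test_modulation_bound(self):
        with pytest.raises(ParameterError):
            OUModelConfig(modulation=1.0)

    def test_seed_gives_identical_spikes(self):
        a = simulate_ou_spike_trains(OUModelConfig(n_units=2, n_trials=10, seed=3))
        b = simulate_ou_spike_trains(OUModelConfig(n_units=2, n_trials=10, seed=3))
        for u in a.spike_times:
            for xa, xb in zip(a.spike_times[u], b.spike_times[u]):
                np.testing.assert_array_equal(xa, xb)

    def test_spike_times_within_trial_and_windows_defined(self):
        sp = simulate_ou_spike_trains(OUModelConfig(n_units=1, n_trials=20, seed=4))
        assert set(sp.windows) >= {"baseline_fixation", "stimulus"}
        for trains in sp.spike_times.values():
            for arr in trains:
                assert np.all((arr >= 0) & (arr <= 400.0))


class TestTunedPopulation:
    def test_outputs_aligned_and_ground_truth_attached(self):
        cm, stim = simulate_tuned_responses(TunedPopConfig(n_repeats=3, seed=0))
        assert cm.counts.shape == (len(stim), cm.n_units)
        assert cm.meta["disruption"] == 0.0
        assert set(stim.columns) >= {"trial", "stimulus_id", "color", "shape"}

    def test_disruption_removes_linear_feature_signal(self):
        def color_slopes(d):
            cm, stim = simulate_tuned_responses(
                TunedPopConfig(noise_sd=0.0, disruption=d, n_repeats=40, seed=1))
            means = np.array([cm.counts[stim.stimulus_id == s].mean(axis=0)
                              for s in np.unique(stim.stimulus_id)])
            c = np.unique(stim[["stimulus_id", "color"]].to_numpy(), axis=0)[:, 1]
            cc = c - c.mean()
            return cc @ (means - means.mean(axis=0)) / (cc @ cc)

        intact = np.abs(color_slopes(0.0))
        disrupted = np.abs(color_slopes(1.0))
        # linear color signal across the population collapses (residual is
        # the matched-variance isotropic noise averaged over repeats)
        assert disrupted.max() < 0.25 * intact.max()


class TestLongitudinalStudy:
    def test_parameters_drift_and_treatment_shifts_structure(self):
        sessions = simulate_longitudinal_study(
            n_days=6, day_step=10, seed=0, with_spikes=False,
            gap_trials=5, foraging_trials=5, pref_trials=5,
            treatment=(30, +0.3))
        forage = [s for s in sessions if s.task == "foraging"]
        assert len(forage) == 6
        s_vals = [s.meta["structure"] for s in forage]
        days = [s.day for s in forage]
        # drift is negative; the +0.3 treatment effect kicks in at day 30
        pre = [v for d, v in zip(days, s_vals) if d < 30]
        assert pre == sorted(pre, reverse=True)
        jump = s_vals[3] - s_vals[2]  # day 30 vs day 20
        assert jump > 0.1
        assert all(s.treatment_flag == (s.day >= 30) for s in sessions)

    def test_reproducible_and_three_tasks_per_day(self):
        kw = dict(n_days=2, seed=5, with_spikes=False, gap_trials=3,
                  foraging_trials=3, pref_trials=3)
        a = simulate_longitudinal_study(**kw)
        b = simulate_longitudinal_study(**kw)
        assert [s.session_id for s in a] == [s.session_id for s in b]
        assert {s.task for s in a if s.day == 0} == {"gap", "foraging", "preferential"}

    def test_spike_population_labels(self):
        sessions = simulate_longitudinal_study(
            n_days=2, seed=1, gap_trials=3, foraging_trials=36, pref_trials=3,
            n_v4=8, n_7a=3)
        sp = [s for s in sessions if s.task == "foraging"][0].spikes
        areas = list(sp.areas.values())
        assert areas.count("V4") == 8 and areas.count("7a") == 3
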