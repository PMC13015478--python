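"""Ground-truth recovery experiments for every estimator in the package.

Each function runs a self-contained simulation experiment against the
synthetic generators' known parameters and returns the measured quantities
(the same experiments back the acceptance checks and the reproducibility
script).  All randomness derives from the ``seed`` argument.

Problem sizes are scaled so the full battery runs in a few minutes on one
CPU; docs/methods.md lists the sizes used and what they do and do not
demonstrate.
"""

from __future__ import annotations

import numpy as np

from .behavior_metrics import entropy_zscore, transition_entropy, transition_matrix
from .core_data import FixationEvent, Session, Trial
from .errors import MatchingFailedError
from .longitudinal_stats import (
    MetricSeries,
    segmented_slope_comparison,
    slope_f_test,
)
from .pipeline import RunConfig, run_pipeline
from .population_metrics import (
    InclusionThresholds,
    autocorrelogram,
    average_autocorrelogram,
    feature_axes_qr,
    fit_intrinsic_timescale,
    loo_decode,
    loo_decode_null,
    noise_correlations,
    rate_matched_subsample,
)
from .synthetic_data import (
    STUDY_SLOPES,
    ForagingSimConfig,
    GainModelConfig,
    OUModelConfig,
    TunedPopConfig,
    _grid_layout,
    simulate_foraging_session,
    simulate_longitudinal_study,
    simulate_ou_spike_trains,
    simulate_tuned_responses,
    simulate_population_counts,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, n)]


# ---------------------------------------------------------------------------
# Transition entropy
# ---------------------------------------------------------------------------


def _uniform_transition_session() -> Session:
    """Foraging session whose pooled transition matrix is exactly uniform.

    One two-fixation trial per ordered location pair (9 x 8 = 72 trials):
    every row of the pooled matrix is uniform over the 8 other locations,
    so the row-sum entropy is exactly 9 * log2(8) = 27 bits.
    """
    layout = _grid_layout(9)
    centers = {it.location_id: (it.x, it.y) for it in layout}
    trials = []
    tid = 0
    for i in range(9):
        for j in range(9):
            if i == j:
                continue
            fix = [FixationEvent(0.0, 200.0, *centers[i], location_id=i),
                   FixationEvent(230.0, 430.0, *centers[j], location_id=j)]
            trials.append(Trial(trial_id=tid, task="foraging", fixations=fix,
                                layout=list(layout), timing={}))
            tid += 1
    return Session(session_id="uniform", day=0, subject_id="oracle", trials=trials)


def entropy_oracle(seed: int, n_sessions: int = 100, n_shuffles: int = 300) -> dict:
    """Closed-form entropy values plus the shuffle-null z calibration.

    * deterministic scan paths -> H = 0 exactly;
    * exactly-uniform 9-location transitions -> H = 27 bits;
    * random foraging (structure 0) -> mean z near 0 across sessions;
    * structured foraging (structure 1) -> z < -2 in nearly all sessions.
    """
    det = simulate_foraging_session(ForagingSimConfig(structure=1.0,
                                                      n_trials=20, seed=seed))
    # a single-start deterministic path gives one successor per row
    det_single = Session(session_id="det", day=0, subject_id="oracle",
                         trials=[det.trials[0]] * 20)
    h_det = transition_entropy(transition_matrix(det_single))
    h_uniform = transition_entropy(transition_matrix(_uniform_transition_session()))

    seeds = _child_seeds(seed, 2 * n_sessions)
    z_random = []
    z_structured = []
    for i in range(n_sessions):
        s0 = simulate_foraging_session(ForagingSimConfig(structure=0.0,
                                                         seed=seeds[i]))
        z_random.append(entropy_zscore(s0, n_shuffles=n_shuffles, seed=seeds[i]).z)
        s1 = simulate_foraging_session(ForagingSimConfig(structure=1.0,
                                                         seed=seeds[n_sessions + i]))
        z_structured.append(
            entropy_zscore(s1, n_shuffles=n_shuffles,
                           seed=seeds[n_sessions + i]).z)
    z_structured = np.asarray(z_structured)
    return {
        "h_deterministic_bits": float(h_det),
        "h_uniform9_bits": float(h_uniform),
        "mean_z_random_foraging": float(np.mean(z_random)),
        "frac_structured_z_below_minus2": float((z_structured < -2).mean()),
        "n_sessions": n_sessions,
    }


# ---------------------------------------------------------------------------
# Noise correlations
# ---------------------------------------------------------------------------


def rsc_oracle(seed: int, n_trials: int = 5000, n_units: int = 50) -> dict:
    """Gain-model rSC against its closed form (lambda*t = 5, sigma_g^2 = 0.01)."""
    s1, s2 = _child_seeds(seed, 2)
    cfg = GainModelConfig(n_units=n_units, n_trials=n_trials,
                          rates_hz=[25.0] * n_units, window_ms=200.0,
                          gain_var=0.01, seed=s1)
    cm = simulate_population_counts(cfg)
    est = noise_correlations(cm).mean_rsc
    rho_true = float(cm.meta["rho_true"][0, 1])
    cm0 = simulate_population_counts(
        GainModelConfig(n_units=n_units, n_trials=n_trials, gain_var=0.0, seed=s2))
    est0 = noise_correlations(cm0).mean_rsc
    return {"rsc_estimate": float(est), "rsc_closed_form": rho_true,
            "rsc_independent": float(est0), "n_trials": n_trials}


# ---------------------------------------------------------------------------
# Rate matching
# ---------------------------------------------------------------------------


def rate_matching_check(seed: int, n_vectors: int = 1000) -> dict:
    """Random feasible rate vectors always land in [20, 30] sp/s; the
    canonical infeasible cases raise the explicit failure."""
    from .core_data import CountMatrix

    rng = np.random.default_rng(seed)
    n_in_band = 0
    n_success = 0
    for _ in range(n_vectors):
        n = int(rng.integers(20, 80))
        rates = rng.uniform(5.0, 60.0, n)
        cm = CountMatrix(np.tile(rates * 0.2, (5, 1)), 200.0, ["V4"] * n,
                         [f"u{i}" for i in range(n)])
        try:
            ids = rate_matched_subsample(cm, seed=int(rng.integers(2**31)))
        except MatchingFailedError:
            continue
        n_success += 1
        kept = rates[[int(u[1:]) for u in ids]]
        n_in_band += bool(20.0 <= kept.mean() <= 30.0)
    infeasible_raises = 0
    for rates in (np.full(10, 5.0), np.full(10, 45.0)):
        cm = CountMatrix(np.tile(rates * 0.2, (5, 1)), 200.0, ["V4"] * 10,
                         [f"u{i}" for i in range(10)])
        try:
            rate_matched_subsample(cm, seed=0)
        except MatchingFailedError:
            infeasible_raises += 1
    return {"frac_in_band": n_in_band / max(n_success, 1),
            "n_success": n_success, "n_vectors": n_vectors,
            "infeasible_raises": infeasible_raises}


# ---------------------------------------------------------------------------
# Intrinsic timescale
# ---------------------------------------------------------------------------


def timescale_recovery(seed: int, n_units: int = 200, n_trials: int = 50,
                       n_null_units: int = 200) -> dict:
    """Recover tau = 50 ms from OU-modulated units; exclude Poisson nulls.

    The recovery fit pools the shuffle-corrected autocorrelogram over
    ``n_units`` simulated unit-sessions of ``n_trials`` trials each; the
    null check fits each homogeneous-Poisson unit separately and counts how
    often the R^2 > 0.5 criterion excludes it.
    """
    s1, s2 = _child_seeds(seed, 2)
    sp = simulate_ou_spike_trains(
        OUModelConfig(n_units=n_units, n_trials=n_trials, rate_hz=30.0,
                      modulation=0.5, tau_ms=50.0, seed=s1),
        include_stimulus_window=False)
    acs = [autocorrelogram(sp.spike_times[u], (0.0, 200.0))
           for u in sp.unit_ids]
    fit = fit_intrinsic_timescale(average_autocorrelogram(acs))

    null_seeds = _child_seeds(s2, n_null_units)
    n_excluded = 0
    for ns in null_seeds:
        spn = simulate_ou_spike_trains(
            OUModelConfig(n_units=1, n_trials=60, rate_hz=30.0,
                          modulation=0.0, tau_ms=50.0, seed=ns),
            include_stimulus_window=False)
        ac = autocorrelogram(spn.spike_times[spn.unit_ids[0]], (0.0, 200.0))
        n_excluded += not fit_intrinsic_timescale(ac).included
    return {"tau_true_ms": 50.0, "tau_fitted_ms": float(fit.tau_ms),
            "fit_r_squared": float(fit.r_squared),
            "frac_poisson_excluded": n_excluded / n_null_units,
            "n_unit_sessions": n_units * n_trials}


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def decoding_checks(seed: int, n_sweep_seeds: int = 20) -> dict:
    """LOO decoding: noiseless recovery, permutation null, disruption sweep."""
    seeds = _child_seeds(seed, n_sweep_seeds + 2)
    cm, stim = simulate_tuned_responses(
        TunedPopConfig(noise_sd=1e-9, disruption=0.0, seed=seeds[-1]))
    r_noiseless = loo_decode(cm, stim["color"])

    cm, stim = simulate_tuned_responses(
        TunedPopConfig(noise_sd=1.0, disruption=0.0, seed=seeds[-2]))
    rng = np.random.default_rng(seeds[-2])
    y_perm = rng.permutation(stim["color"].to_numpy())
    r_perm = loo_decode(cm, y_perm)
    null = loo_decode_null(cm, stim["color"], n_shuffles=1000, seed=seeds[-2])
    null_95 = float(np.quantile(np.abs(null), 0.95))

    sweep = {}
    for d in (0.0, 0.5, 1.0):
        rs = []
        for s in seeds[:n_sweep_seeds]:
            cm_d, stim_d = simulate_tuned_responses(
                TunedPopConfig(noise_sd=1.0, disruption=d, seed=s))
            rs.append(loo_decode(cm_d, stim_d["color"]))
        sweep[d] = float(np.mean(rs))
    return {"r_noiseless": float(r_noiseless),
            "r_feature_permuted": float(r_perm),
            "permutation_null_95": null_95,
            "r_disruption_0": sweep[0.0], "r_disruption_05": sweep[0.5],
            "r_disruption_1": sweep[1.0], "n_sweep_seeds": n_sweep_seeds}


# ---------------------------------------------------------------------------
# QR feature axes
# ---------------------------------------------------------------------------


def qr_checks(seed: int, n_random: int = 10) -> dict:
    """Orthonormality on random inputs and planted-subspace recovery."""
    from scipy.linalg import subspace_angles

    rng = np.random.default_rng(seed)
    c = np.repeat(np.arange(4.0), 4)
    h = np.tile(np.arange(4.0), 4)
    worst_orth = 0.0
    for _ in range(n_random):
        M = rng.uniform(0, 20, (16, 30))
        ax = feature_axes_qr(M, c, h)
        worst_orth = max(worst_orth,
                         float(np.abs(ax.Q.T @ ax.Q - np.eye(2)).max()))
    worst_angle = 0.0
    for _ in range(n_random):
        basis, _ = np.linalg.qr(rng.standard_normal((40, 2)))
        M = (5 * np.outer(c - c.mean(), basis[:, 0])
             + 4 * np.outer(h - h.mean(), basis[:, 1])
             + 0.05 * rng.standard_normal((16, 40)) + 10.0)
        ax = feature_axes_qr(M, c, h)
        ang = float(np.degrees(subspace_angles(ax.Q, basis)).max())
        worst_angle = max(worst_angle, ang)
    return {"max_orthonormality_error": worst_orth,
            "max_principal_angle_deg": worst_angle, "n_random": n_random}


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------


def ablation_check(seed: int, n_repeats: int = 50, dims: int = 50,
                   n_samples: int = 120) -> dict:
    """Concentrated codes collapse faster than distributed ones under ablation.

    At 80% dimension removal (40 of 50), a label carried by 2 dimensions is
    usually lost while a label spread over all dimensions degrades
    gracefully; counts the fraction of paired repeats ordered that way.
    """
    from .population_metrics import ablate_and_decode

    seeds = _child_seeds(seed, n_repeats)
    n_below = 0
    n_remove = int(0.8 * dims)
    for s in seeds:
        rng = np.random.default_rng(s)
        y = rng.standard_normal(n_samples)
        conc = rng.standard_normal((n_samples, dims))
        conc[:, :2] += np.outer(y, np.ones(2)) * 3.0
        w = rng.standard_normal(dims)
        w /= np.linalg.norm(w)
        dist = rng.standard_normal((n_samples, dims)) + np.outer(y, w) * 3.0
        r_conc = ablate_and_decode(conc, y, [n_remove], n_repeats=8,
                                   seed=s)[n_remove]["mean"]
        r_dist = ablate_and_decode(dist, y, [n_remove], n_repeats=8,
                                   seed=s)[n_remove]["mean"]
        n_below += bool(r_conc < r_dist)
    return {"frac_concentrated_below_distributed": n_below / n_repeats,
            "n_repeats": n_repeats, "n_removed": n_remove, "dims": dims}


# ---------------------------------------------------------------------------
# Trend tests
# ---------------------------------------------------------------------------


def trend_calibration(seed: int, n_null: int = 2000, n_points: int = 100,
                      n_segmented: int = 500, alpha: float = 0.05) -> dict:
    """Type-I calibration of the slope F-test and the segmented comparison."""
    rng = np.random.default_rng(seed)
    x = np.arange(float(n_points))
    rejections = 0
    for _ in range(n_null):
        res = slope_f_test(MetricSeries("s", "m", x, rng.standard_normal(n_points)))
        rejections += res.p_value < alpha
    seg_rej = 0
    for _ in range(n_segmented):
        y = 0.02 * x + 2.0 * (x >= n_points / 2) + rng.standard_normal(n_points)
        res = segmented_slope_comparison(MetricSeries("s", "m", x, y),
                                         n_points / 2)
        seg_rej += res.p_value < alpha
    return {"f_test_type1_rate": rejections / n_null,
            "segmented_null_rejection_rate": seg_rej / n_segmented,
            "n_null_series": n_null, "n_segmented_series": n_segmented}


# ---------------------------------------------------------------------------
# End-to-end study
# ---------------------------------------------------------------------------

#: Metrics tracked for sign recovery and the sign each drift injects.
STUDY_EXPECTED_SIGNS = {
    "entropy_z": +1,           # structure decreases -> entropy z increases
    "superfluous_rate": +1,
    "novelty_preference": -1,
    "rsc_v4": -1,              # shared-gain variance decreases
    "tau_ms": -1,
}


def study_sign_recovery(seed: int, n_replicates: int = 10,
                        n_days: int = 45) -> dict:
    """Compressed one-year study: do trend tests recover all drift signs?

    Each replicate simulates ``n_days`` daily sessions spanning the same
    start and end disease severity as the full one-year drifts, runs the
    complete pipeline, and checks the fitted slope sign of all five
    headline metrics against the injected direction.
    """
    scale = 300.0 / n_days
    slopes = {k: v * scale for k, v in STUDY_SLOPES.items()}
    cfg = RunConfig(
        thresholds=InclusionThresholds(min_trials=35, min_v4=10, min_7a=4,
                                       min_cross_pairs=20),
        n_entropy_shuffles=150, timescale_method="population",
        ac_bin_width_ms=2.0, seed=1)
    seeds = _child_seeds(seed, n_replicates)
    n_all = 0
    per_metric = {m: 0 for m in STUDY_EXPECTED_SIGNS}
    for s in seeds:
        sessions = simulate_longitudinal_study(metric_slopes=slopes,
                                               n_days=n_days, seed=s)
        trends = run_pipeline(sessions, cfg).trends.set_index("metric")
        ok = True
        for metric, sign in STUDY_EXPECTED_SIGNS.items():
            hit = (metric in trends.index
                   and np.sign(trends.loc[metric, "slope"]) == sign)
            per_metric[metric] += bool(hit)
            ok &= bool(hit)
        n_all += ok
    return {"frac_replicates_all_signs": n_all / n_replicates,
            "per_metric_recovery": {m: v / n_replicates
                                    for m, v in per_metric.items()},
            "n_replicates": n_replicates, "n_days": n_days}
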