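"""Population metrics: filters, rate matching, rSC, timescales, decoding, axes."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from popdisorg.core_data import CountMatrix
from popdisorg.errors import (
    MatchingFailedError,
    ParameterError,
    UndefinedMetricError,
)
from popdisorg.population_metrics import (
    Autocorrelogram,
    InclusionThresholds,
    ablate_and_decode,
    autocorrelogram,
    average_autocorrelogram,
    feature_axes_qr,
    fit_intrinsic_timescale,
    inclusion_report,
    loo_decode,
    noise_correlations,
    rate_matched_subsample,
    responsiveness_filter,
)
from popdisorg.synthetic_data import (
    GainModelConfig,
    OUModelConfig,
    simulate_ou_spike_trains,
    simulate_population_counts,
)

from conftest import make_spikes


def count_matrix(rates_hz, n_trials=10, window_ms=200.0, areas=None):
    """Constant-count matrix whose per-unit rates are exactly ``rates_hz``."""
    rates = np.asarray(rates_hz, dtype=float)
    counts = np.tile(rates * window_ms / 1000.0, (n_trials, 1))
    return CountMatrix(counts, window_ms, areas or ["V4"] * rates.size,
                       [f"u{i}" for i in range(rates.size)])


class TestResponsivenessFilter:
    @pytest.mark.parametrize("base,stim,active", [
        (4, 5, True),    # 20 -> 25 sp/s: +25%
        (20, 22, True),  # exactly +10%
        (20, 21, False),  # +5%
        (0, 5, True),    # zero baseline, responsive
        (0, 0, False),   # silent unit
    ])
    def test_ten_percent_rule(self, base, stim, active):
        cb = np.full((6, 1), base)
        cs = np.full((6, 1), stim)
        got = responsiveness_filter(make_spikes(cb, cs))
        assert (got == ["u0"]) == active

    def test_inclusion_report_flags_are_threshold_functions(self):
        cb = np.ones((40, 8))
        cs = np.full((40, 8), 3)
        sp = make_spikes(cb, cs, areas=["V4"] * 6 + ["7a"] * 2)
        th = InclusionThresholds(min_trials=35, min_v4=6, min_7a=2, min_cross_pairs=12)
        rep = inclusion_report("s", sp, 40, th)
        assert rep.passed["rsc"] and rep.n_cross_pairs == 12
        th2 = InclusionThresholds(min_trials=35, min_v4=7, min_7a=2, min_cross_pairs=12)
        assert not inclusion_report("s", sp, 40, th2).passed["rsc"]


class TestRateMatching:
    def test_already_in_band_keeps_everyone(self):
        ids = rate_matched_subsample(count_matrix([25.0] * 8), seed=0)
        assert len(ids) == 8

    def test_two_high_two_low_drops_one_high(self):
        # enumeration: removing either 60 gives mean 26.7 in [20, 30]
        ids = rate_matched_subsample(count_matrix([10, 10, 60, 60]), seed=0)
        assert len(ids) == 3 and ("u0" in ids and "u1" in ids)

    def test_all_below_band_fails_explicitly(self):
        with pytest.raises(MatchingFailedError):
            rate_matched_subsample(count_matrix([5.0] * 6), seed=0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ParameterError):
            rate_matched_subsample(count_matrix([25.0] * 4), target=(30.0, 20.0))

    def test_random_feasible_vectors_always_land_in_band(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(20, 60))
            rates = rng.uniform(5.0, 60.0, n)
            cm = count_matrix(rates)
            ids = rate_matched_subsample(cm, seed=int(rng.integers(2**31)))
            kept = rates[[int(u[1:]) for u in ids]]
            assert 20.0 <= kept.mean() <= 30.0


class TestNoiseCorrelations:
    def test_duplicated_units_have_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(5.0, size=(200, 1)).astype(float)
        cm = CountMatrix(np.hstack([x, x]), 200.0, ["V4", "V4"], ["a", "b"])
        res = noise_correlations(cm)
        assert res.mean_rsc == pytest.approx(1.0)

    def test_zero_variance_units_dropped_and_logged(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(5.0, size=(100, 2)).astype(float)
        flat = np.full((100, 1), 3.0)
        cm = CountMatrix(np.hstack([x, flat]), 200.0, ["V4"] * 3, ["a", "b", "c"])
        res = noise_correlations(cm)
        assert res.dropped_zero_variance == ["c"] and res.n_pairs == 1

    def test_cross_area_pair_count(self):
        cm = simulate_population_counts(GainModelConfig(
            n_units=7, n_trials=300, gain_var=0.02,
            areas=["V4"] * 4 + ["7a"] * 3, seed=2))
        res = noise_correlations(cm, "V4-7a")
        assert res.n_pairs == 12

    def test_independent_units_near_zero(self):
        cm = simulate_population_counts(
            GainModelConfig(n_units=30, n_trials=3000, gain_var=0.0, seed=3))
        res = noise_correlations(cm)
        assert abs(res.mean_rsc) < 3 / np.sqrt(3000)


class TestAutocorrelogram:
    def test_trial_locked_structure_is_removed(self):
        # identical spike trains on every trial: correction cancels everything
        train = np.array([10.0, 55.0, 90.0, 140.0, 170.0])
        ac = autocorrelogram([train] * 30, (0.0, 200.0))
        assert np.allclose(ac.values, 0.0, atol=1e-12)

    def test_homogeneous_poisson_is_flat(self):
        rng = np.random.default_rng(4)
        trains = [np.sort(rng.uniform(0, 200, rng.poisson(8))) for _ in range(400)]
        ac = autocorrelogram(trains, (0.0, 200.0))
        assert abs(ac.values.mean()) < 0.02 and np.abs(ac.values).max() < 0.4

    def test_random_shuffle_correction_approximates_exact(self):
        rng = np.random.default_rng(5)
        trains = [np.sort(rng.uniform(0, 200, rng.poisson(10))) for _ in range(60)]
        exact = autocorrelogram(trains, (0.0, 200.0))
        approx = autocorrelogram(trains, (0.0, 200.0), n_shuffles=200, seed=0)
        assert np.corrcoef(exact.values, approx.values)[0, 1] > 0.9 or \
            np.allclose(exact.values, approx.values, atol=0.1)

    def test_too_few_spikes_undefined(self):
        with pytest.raises(UndefinedMetricError):
            autocorrelogram([np.array([10.0]), np.array([])], (0.0, 200.0))

    def test_average_requires_matching_lags(self):
        a = Autocorrelogram(np.arange(1, 5.0), np.zeros(4), 1.0)
        b = Autocorrelogram(np.arange(1, 6.0), np.zeros(5), 1.0)
        with pytest.raises(ParameterError):
            average_autocorrelogram([a, b])


class TestTimescaleFit:
    def test_noiseless_exponential_recovered(self):
        lags = np.arange(1.0, 101.0)
        ac = Autocorrelogram(lags, 0.2 * np.exp(-lags / 50.0), 1.0)
        fit = fit_intrinsic_timescale(ac)
        assert fit.tau_ms == pytest.approx(50.0, abs=0.5)
        assert fit.r_squared > 0.99 and fit.included

    def test_offset_absorbed(self):
        lags = np.arange(1.0, 101.0)
        ac = Autocorrelogram(lags, 0.1 * np.exp(-lags / 30.0) + 0.05, 1.0)
        fit = fit_intrinsic_timescale(ac)
        assert fit.tau_ms == pytest.approx(30.0, abs=1.0)
        assert fit.B == pytest.approx(0.05, abs=0.01)

    def test_ou_units_show_decaying_positive_correlogram(self):
        sp = simulate_ou_spike_trains(OUModelConfig(
            n_units=40, n_trials=60, tau_ms=50.0, modulation=0.5, seed=6),
            include_stimulus_window=False)
        pooled = average_autocorrelogram(
            [autocorrelogram(sp.spike_times[u], (0, 200.0)) for u in sp.unit_ids])
        early = pooled.values[(pooled.lags >= 3) & (pooled.lags <= 20)].mean()
        late = pooled.values[(pooled.lags >= 80) & (pooled.lags <= 100)].mean()
        assert early > late > -0.05 and early > 0.05


class TestLooDecode:
    def _data(self, n=60, p=12, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(n)
        w = rng.standard_normal(p)
        X = np.outer(y, w) + rng.standard_normal((n, p))
        return X, y

    def test_closed_form_matches_explicit_ridge_loop(self):
        from sklearn.linear_model import Ridge

        X, y = self._data()
        lam = 1.7
        r_fast = loo_decode(X, y, ridge_lambda=lam)
        Xs = (X - X.mean(0)) / X.std(0)
        preds = np.empty_like(y)
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            model = Ridge(alpha=lam, solver="cholesky").fit(Xs[mask], y[mask])
            preds[i] = model.predict(Xs[[i]])[0]
        r_loop = np.corrcoef(preds, y)[0, 1]
        assert r_fast == pytest.approx(r_loop, abs=1e-8)

    def test_invariant_to_unit_permutation_and_feature_affine(self):
        X, y = self._data(seed=1)
        r = loo_decode(X, y)
        rng = np.random.default_rng(2)
        assert loo_decode(X[:, rng.permutation(X.shape[1])], y) == pytest.approx(r)
        assert loo_decode(X, 3.0 * y - 7.0) == pytest.approx(r, abs=1e-10)

    def test_refusals(self):
        X, y = self._data(n=12, p=12)
        with pytest.raises(ParameterError):
            loo_decode(X, y, ridge_lambda=0.0)  # ill-posed
        with pytest.raises(ParameterError):
            loo_decode(X[:5], y[:5])  # too few trials
        with pytest.raises(UndefinedMetricError):
            loo_decode(X, np.ones(12))  # degenerate feature

    def test_categorical_one_hot_path(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(np.array(["a", "b", "c"]), 20)
        centers = {"a": np.eye(8)[0], "b": np.eye(8)[1], "c": np.eye(8)[2]}
        X = 3.0 * np.array([centers[c] for c in labels]) + \
            rng.standard_normal((60, 8)) * 0.3
        r = loo_decode(X, labels)
        assert 0.8 < r <= 1.0


class TestFeatureAxes:
    def _planted(self, seed=0, nuisance=0.05):
        rng = np.random.default_rng(seed)
        U = 40
        basis, _ = np.linalg.qr(rng.standard_normal((U, 2)))
        u1, u2 = basis.T
        c = np.repeat(np.arange(4.0), 4)
        h = np.tile(np.arange(4.0), 4)
        M = (5 * np.outer(c - c.mean(), u1) + 4 * np.outer(h - h.mean(), u2)
             + nuisance * rng.standard_normal((16, U)) + 10.0)
        return M, c, h, np.column_stack([u1, u2])

    def test_orthonormal_to_1e10(self):
        M, c, h, _ = self._planted()
        ax = feature_axes_qr(M, c, h)
        assert np.abs(ax.Q.T @ ax.Q - np.eye(2)).max() < 1e-10

    def test_planted_subspace_recovered_within_5_degrees(self):
        for seed in range(5):
            M, c, h, truth = self._planted(seed)
            ax = feature_axes_qr(M, c, h)
            assert np.degrees(subspace_angles(ax.Q, truth)).max() < 5.0

    def test_collinear_codes_refused(self):
        M, c, h, _ = self._planted()
        with pytest.raises(ParameterError):
            feature_axes_qr(M, c, c)

    def test_projection_scaling_bounded(self):
        M, c, h, _ = self._planted()
        ax = feature_axes_qr(M, c, h)
        P = ax.project(M)
        assert np.abs(P).max() <= 1.0 + 1e-12


class TestAblation:
    def test_zero_removal_equals_baseline(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(50)
        X = np.outer(y, rng.standard_normal(20)) + rng.standard_normal((50, 20))
        base = loo_decode(X, y)
        out = ablate_and_decode(X, y, [0], n_repeats=3, seed=1)
        assert np.allclose(out[0]["values"], base)

    def test_single_sufficient_dimension_survives(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(40)
        X = np.tile(y[:, None], (1, 10))  # every dim alone is sufficient
        out = ablate_and_decode(X, y, [9], n_repeats=5, seed=2)
        assert out[9]["mean"] > 0.99

    def test_removal_grid_validated(self):
        X = np.random.default_rng(2).standard_normal((30, 5))
        with pytest.raises(ParameterError):
            ablate_and_decode(X, X[:, 0], [5], n_repeats=2)
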