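"""Population-organization measures for simultaneously recorded units.

* inclusion filters (responsiveness, unit/trial/pair minima);
* firing-rate-matched spike-count noise correlations (rSC);
* intrinsic timescale from the shuffle-corrected, mean-rate-normalized
  spike-count autocorrelogram with an exponential fit;
* leave-one-out cross-validated linear (ridge) population decoding;
* QR-orthogonalized color/shape population axes;
* dimension-ablation decoding on arbitrary feature matrices.

All stochastic steps (rate-matching removals, ablation draws, shuffles)
take explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .core_data import CountMatrix, SpikeData
from .errors import (
    MatchingFailedError,
    ParameterError,
    SessionExcludedError,
    UndefinedMetricError,
)

AREA_PAIRS = ("V4-V4", "7a-7a", "V4-7a")


# ---------------------------------------------------------------------------
# Inclusion filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InclusionThresholds:
    """Session inclusion minima for neuronal analyses.

    Defaults follow the study design: at least 35 completed behavioral
    trials, 45 active V4 units, 10 active 7a units and 100 V4-7a pairs.
    """

    min_trials: int = 35
    min_v4: int = 45
    min_7a: int = 10
    min_cross_pairs: int = 100
    responsiveness_ratio: float = 1.10
    rate_band_hz: tuple[float, float] = (20.0, 30.0)
    r2_threshold: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.rate_band_hz
        if not lo < hi:
            raise ParameterError(f"rate band must be increasing, got {self.rate_band_hz}")


@dataclass
class InclusionReport:
    session_id: str
    n_trials: int
    n_active_v4: int
    n_active_7a: int
    n_cross_pairs: int
    passed: dict[str, bool]


def responsiveness_filter(spikes: SpikeData, *, ratio: float = 1.10,
                          stimulus_windows: Sequence[str] = ("stimulus", "target")) -> list[str]:
    """Unit ids whose mean rate in any stimulus/target window is at least
    ``ratio`` times (default 10% more than) the baseline-fixation rate.

    A unit with zero baseline rate but nonzero stimulus rate is active
    (infinite ratio); an all-zero unit is inactive.
    """
    base_rates = spikes.counts_in_window("baseline_fixation").rates_hz()
    windows = [w for w in stimulus_windows if w in spikes.windows]
    if not windows:
        raise ParameterError("no stimulus/target window defined")
    win_rates = [spikes.counts_in_window(w).rates_hz() for w in windows]
    active = []
    for j, uid in enumerate(spikes.unit_ids):
        b = base_rates[j]
        for rates in win_rates:
            r = rates[j]
            if (b == 0 and r > 0) or (b > 0 and r >= ratio * b - 1e-12):
                active.append(uid)
                break
    return active


def inclusion_report(session_id: str, spikes: SpikeData, n_trials: int,
                     thresholds: InclusionThresholds = InclusionThresholds()) -> InclusionReport:
    """Evaluate the session against all neuronal inclusion filters."""
    active = set(responsiveness_filter(spikes, ratio=thresholds.responsiveness_ratio))
    areas = spikes.areas
    n_v4 = sum(1 for u in active if areas[u] == "V4")
    n_7a = sum(1 for u in active if areas[u] == "7a")
    n_pairs = n_v4 * n_7a
    enough_trials = n_trials >= thresholds.min_trials
    passed = {
        "rsc": enough_trials and n_v4 >= thresholds.min_v4
        and n_7a >= thresholds.min_7a and n_pairs >= thresholds.min_cross_pairs,
        "timescale": enough_trials and n_v4 >= thresholds.min_v4,
        "decoding": enough_trials and (n_v4 + n_7a) > 0,
    }
    return InclusionReport(session_id=session_id, n_trials=n_trials,
                           n_active_v4=n_v4, n_active_7a=n_7a,
                           n_cross_pairs=n_pairs, passed=passed)


# ---------------------------------------------------------------------------
# Firing-rate matching and noise correlations
# ---------------------------------------------------------------------------


def rate_matched_subsample(counts: CountMatrix,
                           target: tuple[float, float] = (20.0, 30.0),
                           min_units: int = 2, seed: Optional[int] = 0,
                           unit_ids: Optional[Sequence[str]] = None) -> list[str]:
    """Randomly drop units until the mean baseline rate falls in ``target``.

    While the mean rate is above the band a uniformly random unit with rate
    above the current mean is removed; while below, a random unit below the
    current mean.  This directed variant of random dropping guarantees
    termination: each step moves the mean toward the band or the procedure
    fails explicitly (band unreachable, or the population would shrink
    below ``min_units``).
    """
    lo, hi = target
    if not lo < hi:
        raise ParameterError(f"target band must be increasing, got {target}")
    rng = np.random.default_rng(seed)
    ids = list(unit_ids) if unit_ids is not None else list(counts.unit_ids)
    idx = {u: i for i, u in enumerate(counts.unit_ids)}
    rates = counts.rates_hz()
    kept = list(ids)
    if len(kept) < min_units:
        raise MatchingFailedError(f"only {len(kept)} units, need >= {min_units}")
    while True:
        r = np.array([rates[idx[u]] for u in kept])
        mean = r.mean()
        if lo <= mean <= hi:
            return kept
        if len(kept) <= min_units:
            raise MatchingFailedError(
                f"cannot reach rate band {target} without dropping below {min_units} units")
        if mean > hi:
            cand = np.flatnonzero(r > mean)
        else:
            cand = np.flatnonzero(r < mean)
        if cand.size == 0:
            raise MatchingFailedError(
                f"rate matching stuck at mean {mean:.2f} sp/s (all rates equal)")
        kept.pop(int(rng.choice(cand)))


@dataclass
class CorrelationResult:
    """Mean pairwise spike-count (noise) correlation for one area pair."""

    area_pair: str
    mean_rsc: float
    n_pairs: int
    included_unit_ids: list[str]
    mean_rate_after_matching_hz: float
    dropped_zero_variance: list[str] = field(default_factory=list)


def noise_correlations(counts: CountMatrix, area_pair: str = "V4-V4",
                       matched_ids: Optional[Sequence[str]] = None,
                       min_pairs: int = 1) -> CorrelationResult:
    """Mean Pearson correlation of trial-to-trial counts over unit pairs.

    Within-area pairs exclude self-pairs and double counting; cross-area
    pairs take every (V4, 7a) combination.  Units with zero count variance
    cannot be correlated; their pairs are dropped and the units reported.
    """
    if area_pair not in AREA_PAIRS:
        raise ParameterError(f"area_pair must be one of {AREA_PAIRS}")
    ids = list(matched_ids) if matched_ids is not None else list(counts.unit_ids)
    idx = {u: i for i, u in enumerate(counts.unit_ids)}
    areas = {u: counts.areas[idx[u]] for u in ids}
    X = counts.counts[:, [idx[u] for u in ids]]
    var = X.var(axis=0)
    dropped = [u for u, v in zip(ids, var) if v == 0]
    keep = [i for i, u in enumerate(ids) if u not in dropped]
    ids = [ids[i] for i in keep]
    X = X[:, keep]
    a1, a2 = area_pair.split("-")
    g1 = [i for i, u in enumerate(ids) if areas[u] == a1]
    g2 = [i for i, u in enumerate(ids) if areas[u] == a2]
    if a1 == a2:
        if len(g1) < 2:
            raise UndefinedMetricError(f"need >= 2 {a1} units, have {len(g1)}")
        sub = np.corrcoef(X[:, g1], rowvar=False)
        iu = np.triu_indices(len(g1), k=1)
        vals = sub[iu]
    else:
        if not g1 or not g2:
            raise UndefinedMetricError(f"need units in both {a1} and {a2}")
        c = np.corrcoef(X, rowvar=False)
        vals = c[np.ix_(g1, g2)].ravel()
    if vals.size < min_pairs:
        raise SessionExcludedError(
            f"{vals.size} {area_pair} pairs < required minimum {min_pairs}")
    rates = counts.rates_hz()[[idx[u] for u in ids]]
    return CorrelationResult(area_pair=area_pair, mean_rsc=float(vals.mean()),
                             n_pairs=int(vals.size), included_unit_ids=ids,
                             mean_rate_after_matching_hz=float(rates.mean()),
                             dropped_zero_variance=dropped)


# ---------------------------------------------------------------------------
# Autocorrelogram and intrinsic timescale
# ---------------------------------------------------------------------------


@dataclass
class Autocorrelogram:
    """Shuffle-corrected, mean-rate-normalized spike-count autocorrelogram.

    ``values[k]`` is the excess coincidence rate at ``lags[k]`` (ms): the
    within-trial bin-pair product minus its across-trial (shuffled)
    expectation, per bin pair, divided by the squared mean count per bin.
    A unit with no temporal structure beyond a trial-locked rate has values
    near 0 at every lag; a latent with timescale tau leaves an
    exp(-lag/tau) profile.
    """

    lags: np.ndarray     # ms, positive
    values: np.ndarray
    bin_width_ms: float
    n_trials: int = 0
    mean_rate_hz: float = float("nan")


def _bin_trains(spike_trains: Sequence[np.ndarray], window: tuple[float, float],
                bin_width: float) -> np.ndarray:
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + np.arange(n_bins + 1) * bin_width
    out = np.zeros((len(spike_trains), n_bins), dtype=np.int64)
    for i, st in enumerate(spike_trains):
        st = np.asarray(st, dtype=float)
        st = st[(st >= lo) & (st < hi)]
        if st.size:
            out[i] = np.histogram(st, bins=edges)[0]
    return out


def autocorrelogram(spike_trains: Sequence[np.ndarray],
                    window: tuple[float, float] = (0.0, 200.0),
                    bin_width: float = 1.0, max_lag_ms: float = 100.0,
                    n_shuffles: Optional[int] = None,
                    seed: Optional[int] = None) -> Autocorrelogram:
    """Shuffle-corrected autocorrelogram of one unit's spike trains.

    The raw histogram counts spike-pair coincidences within trials at each
    positive lag; the correction subtracts the expected histogram when
    spike trains are paired across *different* trials, removing any
    trial-locked (stimulus- or slow-drift-driven) structure.  By default
    the correction is the exact average over all ordered cross-trial
    pairings; passing ``n_shuffles`` uses that many random trial
    permutations instead.
    """
    X = _bin_trains(spike_trains, window, bin_width)
    if X.sum() < 2:
        raise UndefinedMetricError("fewer than 2 spikes in the analysis window")
    m, b = X.shape
    if m < 2:
        raise UndefinedMetricError("need at least 2 trials for shuffle correction")
    n_lags = min(int(round(max_lag_ms / bin_width)), b - 1)
    lags = (np.arange(1, n_lags + 1)) * bin_width
    Xf = X.astype(float)
    raw = np.empty(n_lags)
    shuf = np.empty(n_lags)
    S = Xf.sum(axis=0)
    for k in range(1, n_lags + 1):
        within = float((Xf[:, :-k] * Xf[:, k:]).sum()) / m
        raw[k - 1] = within
        if n_shuffles is None:
            cross = float((S[:-k] * S[k:]).sum())
            shuf[k - 1] = (cross - within * m) / (m * (m - 1))
        else:
            rng = np.random.default_rng(seed)
            acc = 0.0
            for _ in range(n_shuffles):
                perm = rng.permutation(m)
                acc += float((Xf[:, :-k] * Xf[perm, k:]).sum()) / m
            shuf[k - 1] = acc / n_shuffles
    n_pairs = b - np.arange(1, n_lags + 1, dtype=float)
    mbar = Xf.mean()  # mean count per bin
    if mbar == 0:
        raise UndefinedMetricError("zero mean rate")
    values = (raw - shuf) / (n_pairs * mbar * mbar)
    rate_hz = mbar / (bin_width / 1000.0)
    return Autocorrelogram(lags=lags, values=values, bin_width_ms=bin_width,
                           n_trials=m, mean_rate_hz=rate_hz)


def unit_autocorrelogram(spikes: SpikeData, unit_id: str, **kwargs) -> Autocorrelogram:
    """Autocorrelogram of one unit in the baseline-fixation window."""
    window = kwargs.pop("window", spikes.windows["baseline_fixation"])
    return autocorrelogram(spikes.spike_times[unit_id], window=window, **kwargs)


def average_autocorrelogram(acs: Sequence[Autocorrelogram]) -> Autocorrelogram:
    """Pool autocorrelograms across units by averaging their values."""
    if not acs:
        raise ParameterError("no autocorrelograms to average")
    lags = acs[0].lags
    for ac in acs[1:]:
        if not np.array_equal(ac.lags, lags):
            raise ParameterError("autocorrelograms have mismatched lag grids")
    return Autocorrelogram(
        lags=lags.copy(),
        values=np.mean([ac.values for ac in acs], axis=0),
        bin_width_ms=acs[0].bin_width_ms,
        n_trials=sum(ac.n_trials for ac in acs),
        mean_rate_hz=float(np.mean([ac.mean_rate_hz for ac in acs])),
    )


@dataclass
class TimescaleFit:
    """Exponential fit A*exp(-lag/tau) + B to an autocorrelogram."""

    A: float
    tau_ms: float
    B: float
    r_squared: float
    included: bool
    fit_lag_range_ms: tuple[float, float]

    def predict(self, lags: np.ndarray) -> np.ndarray:
        return self.A * np.exp(-np.asarray(lags) / self.tau_ms) + self.B


def fit_intrinsic_timescale(ac: Autocorrelogram,
                            fit_range_ms: tuple[float, float] = (3.0, 100.0),
                            tau_bounds_ms: tuple[float, float] = (1.0, 500.0),
                            r2_threshold: float = 0.5) -> TimescaleFit:
    """Fit A*exp(-lag/tau) + B over lags in ``fit_range_ms`` (default 3-100 ms).

    Fitting starts 3 ms after the zero lag to avoid refractory-period
    structure.  The unit is included iff the goodness of fit R^2 exceeds
    ``r2_threshold`` (default 0.5); non-convergent fits are excluded with
    ``tau_ms`` = NaN.
    """
    lo, hi = fit_range_ms
    sel = (ac.lags >= lo) & (ac.lags <= hi)
    lags = ac.lags[sel]
    y = ac.values[sel]
    if lags.size < 4:
        raise UndefinedMetricError("too few lags in the fit range")

    def model(lag, a, tau, b):
        return a * np.exp(-lag / tau) + b

    best = None
    span = max(y.max() - y.min(), 1e-12)
    for tau0 in (5.0, 20.0, 80.0):
        try:
            p0 = (span, tau0, float(y[-10:].mean()))
            popt, _ = optimize.curve_fit(
                model, lags, y, p0=p0,
                bounds=([-np.inf, tau_bounds_ms[0], -np.inf],
                        [np.inf, tau_bounds_ms[1], np.inf]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ss_res = float(np.sum((y - model(lags, *popt)) ** 2))
        if best is None or ss_res < best[1]:
            best = (popt, ss_res)
    if best is None:
        return TimescaleFit(A=float("nan"), tau_ms=float("nan"), B=float("nan"),
                            r_squared=float("nan"), included=False,
                            fit_lag_range_ms=fit_range_ms)
    popt, ss_res = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return TimescaleFit(A=float(popt[0]), tau_ms=float(popt[1]), B=float(popt[2]),
                        r_squared=r2, included=bool(r2 > r2_threshold),
                        fit_lag_range_ms=fit_range_ms)


# ---------------------------------------------------------------------------
# Leave-one-out population decoding
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _loo_smoother(X: np.ndarray, ridge_lambda: float) -> tuple[np.ndarray, np.ndarray]:
    """Hat matrix and its diagonal for ridge with an unpenalized intercept.

    For penalized least squares the exact leave-one-out prediction is
    (yhat_i - h_ii y_i) / (1 - h_ii), so LOO decoding never needs n
    separate fits.
    """
    n = X.shape[0]
    Xa = np.column_stack([_standardize(X), np.ones(n)])
    pen = np.full(Xa.shape[1], float(ridge_lambda))
    pen[-1] = 0.0
    G = Xa.T @ Xa + np.diag(pen)
    H = Xa @ np.linalg.solve(G, Xa.T)
    return H, np.diag(H).copy()


def _loo_predict(H: np.ndarray, h: np.ndarray, y: np.ndarray) -> np.ndarray:
    denom = 1.0 - h
    if np.any(denom <= 1e-10):
        raise UndefinedMetricError("leverage ~1: a trial is unpredictable from the rest")
    return (H @ y - h * y) / denom


def _is_categorical(y: np.ndarray) -> bool:
    return y.dtype.kind in "OUS" or y.dtype == bool


def loo_decode(counts: Union[CountMatrix, np.ndarray], feature: Sequence,
               ridge_lambda: float = 1.0) -> float:
    """Leave-one-out cross-validated linear decoding correlation.

    Each trial's feature value is predicted by ridge regression (neurons as
    regressors, counts standardized, intercept unpenalized) fit on all
    other trials; the score is the Pearson correlation between predictions
    and truth.  Categorical features are decoded via one-hot targets and
    scored as the mean per-dimension correlation.  With ``ridge_lambda=0``
    and more units than trials the problem is ill-posed and refused.
    """
    X = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts, float)
    y = np.asarray(feature)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ParameterError("feature length must equal the number of trials")
    n, p = X.shape
    if n < 10:
        raise ParameterError(f"need >= 10 trials, got {n}")
    if ridge_lambda < 0:
        raise ParameterError("ridge_lambda must be >= 0")
    if ridge_lambda == 0 and p >= n - 1:
        raise ParameterError("more units than trials with no regularization is ill-posed")
    H, h = _loo_smoother(X, ridge_lambda)
    if _is_categorical(y):
        classes = np.unique(y)
        if classes.size < 2:
            raise UndefinedMetricError("feature has a single class")
        rs = []
        for c in classes:
            t = (y == c).astype(float)
            pred = _loo_predict(H, h, t)
            rs.append(stats.pearsonr(pred, t)[0])
        return float(np.mean(rs))
    y = y.astype(float)
    if np.var(y) == 0:
        raise UndefinedMetricError("feature has zero variance")
    pred = _loo_predict(H, h, y)
    return float(stats.pearsonr(pred, y)[0])


def loo_decode_null(counts: Union[CountMatrix, np.ndarray], feature: Sequence,
                    n_shuffles: int = 1000, seed: Optional[int] = 0,
                    ridge_lambda: float = 1.0) -> np.ndarray:
    """Permutation null of the LOO decoding correlation.

    Permutes the feature against the responses; the hat matrix is reused,
    so each draw costs one matrix-vector product.
    """
    X = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts, float)
    y = np.asarray(feature, dtype=float)
    if np.var(y) == 0:
        raise UndefinedMetricError("feature has zero variance")
    rng = np.random.default_rng(seed)
    H, h = _loo_smoother(X, ridge_lambda)
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        yp = y[rng.permutation(y.size)]
        pred = _loo_predict(H, h, yp)
        out[s] = stats.pearsonr(pred, yp)[0]
    return out


# ---------------------------------------------------------------------------
# QR-orthogonalized feature axes
# ---------------------------------------------------------------------------


@dataclass
class FeatureAxes:
    """Orthonormal color/shape axes in population space.

    ``Q`` has one orthonormal column per feature (color first).  Axes are
    built by PCA on the stimulus-mean responses, regressing the PCA
    projections on each feature code, mapping the two regression directions
    back to unit space and orthogonalizing them by QR decomposition.
    Projections are scaled per session by subtracting the mean and dividing
    by the maximum response.
    """

    Q: np.ndarray               # (n_units, 2), orthonormal columns
    pca_components: np.ndarray  # (k, n_units)
    pca_var_retained: float
    mean_response: np.ndarray   # (n_units,) stimulus-mean used for centering
    scaling: tuple[np.ndarray, float]  # (per-axis mean, max abs) from the fit set

    def project(self, responses: np.ndarray, *, rescale: bool = True) -> np.ndarray:
        """Project responses (trials x units) onto the orthogonalized axes."""
        P = (np.asarray(responses, float) - self.mean_response) @ self.Q
        if rescale:
            mean, mx = self.scaling
            P = (P - mean) / mx
        return P


def feature_axes_qr(mean_responses: np.ndarray, color_codes: Sequence[float],
                    shape_codes: Sequence[float], pca_var: float = 0.90) -> FeatureAxes:
    """Orthogonalized population axes for color and shape.

    ``mean_responses`` is stimuli x units (the average response to each
    stimulus).  Refuses collinear color/shape codes, for which the two axes
    are unidentifiable.
    """
    M = np.asarray(mean_responses, dtype=float)
    c = np.asarray(color_codes, dtype=float)
    s = np.asarray(shape_codes, dtype=float)
    if M.ndim != 2 or c.size != M.shape[0] or s.size != M.shape[0]:
        raise ParameterError("codes must have one entry per stimulus row")
    if np.unique(c).size < 2 or np.unique(s).size < 2:
        raise ParameterError("each feature needs >= 2 distinct values")
    cc, sc = c - c.mean(), s - s.mean()
    r = float(np.dot(cc, sc) / math.sqrt(np.dot(cc, cc) * np.dot(sc, sc)))
    if abs(r) > 0.999:
        raise ParameterError("color and shape codes are collinear; axes unidentifiable")

    from sklearn.decomposition import PCA

    if not 0 < pca_var <= 1:
        raise ParameterError("pca_var must lie in (0, 1]")
    n_max = min(M.shape[0] - 1, M.shape[1])
    pca = PCA(n_components=n_max, svd_solver="full")
    Z = pca.fit_transform(M)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, pca_var) + 1)
    k = max(k, 2)
    Z = Z[:, :k]
    comps = pca.components_[:k]

    # simple regression of each PCA coordinate on the (centered) feature code
    b_c = Z.T @ cc / np.dot(cc, cc)
    b_s = Z.T @ sc / np.dot(sc, sc)
    A = np.column_stack([comps.T @ b_c, comps.T @ b_s])
    Q, R = np.linalg.qr(A)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs

    mean_response = M.mean(axis=0)
    P = (M - mean_response) @ Q
    mx = float(np.abs(P - P.mean(axis=0)).max())
    scaling = (P.mean(axis=0), mx if mx > 0 else 1.0)
    return FeatureAxes(Q=Q, pca_components=comps,
                       pca_var_retained=float(cum[k - 1]),
                       mean_response=mean_response, scaling=scaling)


# ---------------------------------------------------------------------------
# Dimension ablation
# ---------------------------------------------------------------------------


def ablate_and_decode(features: np.ndarray, labels: Sequence,
                      n_remove: Sequence[int], n_repeats: int = 20,
                      seed: Optional[int] = 0,
                      ridge_lambda: float = 1.0) -> dict[int, dict]:
    """Decoding as a function of randomly removed feature dimensions.

    For each entry of ``n_remove``, repeats ``n_repeats`` times: drop that
    many uniformly random dimensions and run :func:`loo_decode` on the
    rest.  Returns ``{n_removed: {"mean", "sd", "values"}}``.
    """
    X = np.asarray(features, dtype=float)
    d = X.shape[1]
    n_remove = [int(n) for n in n_remove]
    if any(n < 0 or n >= d for n in n_remove):
        raise ParameterError(f"n_remove values must lie in [0, {d - 1}]")
    rng = np.random.default_rng(seed)
    out: dict[int, dict] = {}
    for n in n_remove:
        vals = []
        for _ in range(n_repeats):
            keep = rng.permutation(d)[: d - n]
            vals.append(loo_decode(X[:, np.sort(keep)], labels, ridge_lambda))
        vals = np.asarray(vals)
        out[n] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0)),
                  "values": vals}
    return out
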