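"""Synthetic sessions and spike data with analytically known ground truth.

Every downstream estimator in this package (transition entropy, noise
correlations, intrinsic timescales, population decoding, trend tests) has a
generator here whose parameters *are* the quantity the estimator recovers:

* foraging scan paths with a tunable structure parameter ``s`` mixing a
  deterministic nearest-unvisited-neighbor policy (``s=1``) with uniform
  choice among the other locations (``s=0``);
* gap-task trials with an exact superfluous-saccade probability;
* preferential-looking trials with an exact long-run novelty preference and
  switch rate (alternating exponential dwells);
* doubly stochastic (shared gamma gain) Poisson counts with a closed-form
  pairwise spike-count correlation;
* Poisson spike trains rate-modulated by an Ornstein-Uhlenbeck latent with
  known timescale tau;
* tuned population responses to a color x shape stimulus grid with a
  disruption parameter ``d`` that removes population-level feature signal
  while sparing most single-unit tuning;
* a longitudinal study in which all of these parameters drift linearly
  across days, with an optional treatment epoch.

All generators are exactly reproducible from their seed and attach their
ground-truth parameters to the returned object's ``meta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    CountMatrix,
    FixationEvent,
    LayoutItem,
    SaccadeEvent,
    Session,
    SpikeData,
    Trial,
)
from .errors import ParameterError

__all__ = [
    "ForagingSimConfig",
    "GainModelConfig",
    "OUModelConfig",
    "TunedPopConfig",
    "simulate_foraging_session",
    "simulate_gap_session",
    "simulate_preferential_session",
    "simulate_population_counts",
    "simulate_ou_spike_trains",
    "simulate_tuned_responses",
    "simulate_longitudinal_study",
    "gain_model_rho",
]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _grid_layout(n_locations: int, spacing: float = 5.0) -> list[LayoutItem]:
    """Near-square grid of stimulus locations centered on the screen.

    Even location ids are targets, odd ids distractors."""
    side = math.ceil(math.sqrt(n_locations))
    items = []
    for k in range(n_locations):
        r, c = divmod(k, side)
        x = (c - (side - 1) / 2) * spacing
        y = ((side - 1) / 2 - r) * spacing
        items.append(LayoutItem(k, x, y, "target" if k % 2 == 0 else "distractor"))
    return items


# ---------------------------------------------------------------------------
# Foraging
# ---------------------------------------------------------------------------


@dataclass
class ForagingSimConfig:
    """Configuration for the visual-foraging scan-path generator.

    ``structure`` mixes a deterministic nearest-unvisited-neighbor policy
    (1.0) with a uniform choice over the other ``n_locations - 1`` items
    (0.0); intermediate values pick the deterministic move with that
    probability on each step.
    """

    n_locations: int = 9
    n_trials: int = 25
    structure: float = 0.5
    n_fixations_per_trial: Optional[int] = None
    fixation_duration_mean: float = 250.0
    fixation_duration_sd: float = 50.0
    jitter_deg: float = 0.3
    spacing_deg: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.structure <= 1.0:
            raise ParameterError("structure must lie in [0, 1]")
        if self.n_locations < 2:
            raise ParameterError("need at least 2 locations")


def simulate_foraging_session(cfg: ForagingSimConfig, *, day: int = 0,
                              subject_id: str = "sim",
                              session_id: Optional[str] = None) -> Session:
    """Generate one foraging session of fixation sequences over a stimulus grid.

    Rewards follow the foraging rule: the first visit to a target location is
    rewarded, revisits and distractor fixations are not.  Fixations carry
    their true ``location_id`` (positions are jittered around the item
    centers, well inside the default 2 degree assignment radius).
    """
    rng = _rng(cfg.seed)
    layout = _grid_layout(cfg.n_locations, cfg.spacing_deg)
    centers = np.array([[it.x, it.y] for it in layout])
    n_fix = cfg.n_fixations_per_trial or cfg.n_locations
    trials = []
    for tid in range(cfg.n_trials):
        loc = int(rng.integers(cfg.n_locations))
        visited = {loc}
        seq = [loc]
        for _ in range(n_fix - 1):
            if rng.random() < cfg.structure:
                # deterministic move: nearest unvisited, else nearest other
                cand = [k for k in range(cfg.n_locations) if k not in visited]
                if not cand:
                    cand = [k for k in range(cfg.n_locations) if k != loc]
                d = np.hypot(centers[cand, 0] - centers[loc, 0],
                             centers[cand, 1] - centers[loc, 1])
                loc = cand[int(np.argmin(d))]  # lowest id wins ties (cand sorted)
            else:
                others = [k for k in range(cfg.n_locations) if k != loc]
                loc = others[int(rng.integers(len(others)))]
            visited.add(loc)
            seq.append(loc)

        fixations, saccades, rewarded = [], [], set()
        t = 200.0  # initial central fixation period precedes the array
        seen: set[int] = set()
        for i, k in enumerate(seq):
            dur = max(50.0, rng.normal(cfg.fixation_duration_mean,
                                       cfg.fixation_duration_sd))
            x = centers[k, 0] + rng.normal(0, cfg.jitter_deg)
            y = centers[k, 1] + rng.normal(0, cfg.jitter_deg)
            fixations.append(FixationEvent(t, t + dur, x, y, location_id=k))
            if layout[k].role == "target" and k not in seen:
                rewarded.add(i)
            seen.add(k)
            if i + 1 < len(seq):
                saccades.append(SaccadeEvent(t + dur, *centers[seq[i + 1]]))
            t += dur + 30.0  # saccade in flight
        trials.append(Trial(trial_id=tid, task="foraging", fixations=fixations,
                            saccades=saccades, layout=list(layout),
                            timing={"array_onset": 200.0},
                            rewarded_fixation_ids=rewarded, completed=True))
    sid = session_id or f"foraging-{subject_id}-d{day}"
    return Session(session_id=sid, day=day, subject_id=subject_id, trials=trials,
                   meta={"generator": "foraging", "structure": cfg.structure,
                         "n_locations": cfg.n_locations, "seed": cfg.seed})


# ---------------------------------------------------------------------------
# Gap task
# ---------------------------------------------------------------------------

_GAP_TARGETS = [(8.0, 0.0), (0.0, 8.0), (-8.0, 0.0), (0.0, -8.0)]


def simulate_gap_session(p_superfluous: float, n_trials: int = 100,
                         gap_ms: float = 200.0, seed: int = 0, *, day: int = 0,
                         subject_id: str = "sim",
                         session_id: Optional[str] = None) -> Session:
    """Gap-task session: fixation spot offset precedes target onset by ``gap_ms``.

    Each trial independently contains, with probability ``p_superfluous``, a
    saccade launched strictly inside the gap that leaves the 1 degree
    fixation window.  Every trial ends with a rewarded saccade to the target
    within 400 ms of target onset.
    """
    if not 0.0 <= p_superfluous <= 1.0:
        raise ParameterError("p_superfluous must lie in [0, 1]")
    if gap_ms < 0:
        raise ParameterError("gap_ms must be non-negative")
    rng = _rng(seed)
    fix_off = 500.0
    t_on = fix_off + gap_ms
    trials = []
    for tid in range(n_trials):
        tx, ty = _GAP_TARGETS[int(rng.integers(4))]
        layout = [LayoutItem(0, 0.0, 0.0, "fixation_spot"),
                  LayoutItem(1, tx, ty, "saccade_target")]
        fixations = [FixationEvent(0.0, fix_off, rng.normal(0, 0.2),
                                   rng.normal(0, 0.2), location_id=0)]
        saccades = []
        superfluous = bool(rng.random() < p_superfluous)
        if superfluous and gap_ms > 0:
            onset = fix_off + rng.uniform(0.05, 0.95) * gap_ms
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(3.0, 6.0)
            saccades.append(SaccadeEvent(onset, r * np.cos(ang), r * np.sin(ang)))
        rt = rng.uniform(120.0, 350.0)
        saccades.append(SaccadeEvent(t_on + rt, tx + rng.normal(0, 0.3),
                                     ty + rng.normal(0, 0.3)))
        fixations.append(FixationEvent(t_on + rt + 30.0, t_on + rt + 330.0,
                                       tx, ty, location_id=1))
        trials.append(Trial(trial_id=tid, task="gap", fixations=fixations,
                            saccades=saccades, layout=layout,
                            timing={"fixation_spot_offset": fix_off,
                                    "target_onset": t_on},
                            rewarded_fixation_ids={1}, completed=True))
    sid = session_id or f"gap-{subject_id}-d{day}"
    return Session(session_id=sid, day=day, subject_id=subject_id, trials=trials,
                   meta={"generator": "gap", "p_superfluous": p_superfluous,
                         "gap_ms": gap_ms, "seed": seed})


# ---------------------------------------------------------------------------
# Preferential looking
# ---------------------------------------------------------------------------


def simulate_preferential_session(pref_novel: float, switch_rate: float = 2.0,
                                  dwell_mean: float = 250.0, n_trials: int = 30,
                                  seed: int = 0, *, day: int = 0,
                                  subject_id: str = "sim",
                                  session_id: Optional[str] = None) -> Session:
    """Free-viewing session over one novel and one familiar image.

    Viewing alternates between the two images in exponential dwell segments
    whose means are chosen so that the long-run fraction of viewing time on
    the novel image equals ``pref_novel`` and the expected number of
    image-to-image switches per second equals ``switch_rate``.  Each trial
    accumulates 1000 ms of total image viewing (the reward criterion);
    segments are split into fixations of mean duration ``dwell_mean`` ms.
    """
    if not 0.0 <= pref_novel <= 1.0:
        raise ParameterError("pref_novel must lie in [0, 1]")
    if switch_rate < 0:
        raise ParameterError("switch_rate must be non-negative")
    rng = _rng(seed)
    total_ms = 1000.0
    trials = []
    for tid in range(n_trials):
        novel_side = 1 if rng.random() < 0.5 else -1
        layout = [LayoutItem(0, 6.0 * novel_side, 0.0, "novel_image"),
                  LayoutItem(1, -6.0 * novel_side, 0.0, "familiar_image")]
        # segment means per state; a state with zero mean is never entered
        if switch_rate > 0 and 0.0 < pref_novel < 1.0:
            mean_n = 2000.0 * pref_novel / switch_rate
            mean_f = 2000.0 * (1.0 - pref_novel) / switch_rate
        else:
            mean_n = mean_f = math.inf
        state = 0 if rng.random() < pref_novel else 1  # 0 = novel
        segments = []
        acc = 0.0
        while acc < total_ms:
            mean = mean_n if state == 0 else mean_f
            dur = rng.exponential(mean) if math.isfinite(mean) else total_ms - acc
            dur = min(dur, total_ms - acc)
            if dur > 0:
                segments.append((state, dur))
                acc += dur
            state = 1 - state
        fixations = []
        t = 250.0
        for st, seg_dur in segments:
            cx, cy = (layout[st].x, layout[st].y)
            remaining = seg_dur
            while remaining > 1e-9:
                dur = max(60.0, rng.normal(dwell_mean, dwell_mean / 4))
                dur = min(dur, remaining)
                fixations.append(FixationEvent(t, t + dur,
                                               cx + rng.normal(0, 0.8),
                                               cy + rng.normal(0, 0.8),
                                               location_id=st))
                t += dur + 25.0
                remaining -= dur
        trials.append(Trial(trial_id=tid, task="preferential",
                            fixations=fixations, saccades=[], layout=layout,
                            timing={"image_onset": 250.0}, completed=True))
    sid = session_id or f"pref-{subject_id}-d{day}"
    return Session(session_id=sid, day=day, subject_id=subject_id, trials=trials,
                   meta={"generator": "preferential", "pref_novel": pref_novel,
                         "switch_rate": switch_rate, "seed": seed})


# ---------------------------------------------------------------------------
# Shared-gain (doubly stochastic) Poisson counts
# ---------------------------------------------------------------------------


@dataclass
class GainModelConfig:
    """Doubly stochastic Poisson model: counts_i | g ~ Poisson(lambda_i * t * g).

    The gain g is shared by all units within a trial, gamma-distributed with
    mean 1 and variance ``gain_var``, which induces a closed-form pairwise
    spike-count correlation (see :func:`gain_model_rho`).
    """

    n_units: int = 50
    n_trials: int = 1000
    rates_hz: Optional[Sequence[float]] = None  # default: all 25 sp/s
    window_ms: float = 200.0
    gain_var: float = 0.01
    areas: Optional[Sequence[str]] = None  # default: all V4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_var < 0:
            raise ParameterError("gain_var must be >= 0")
        if self.rates_hz is not None and np.any(np.asarray(self.rates_hz) <= 0):
            raise ParameterError("rates must be positive")


def gain_model_rho(rates_hz: np.ndarray, window_ms: float,
                   gain_var: float) -> np.ndarray:
    """Closed-form pairwise count correlation of the shared-gain model.

    With mu_i = lambda_i * t, Cov(N_i, N_j) = mu_i mu_j sigma_g^2 (i != j)
    and Var(N_i) = mu_i + mu_i^2 sigma_g^2.
    """
    mu = np.asarray(rates_hz, dtype=float) * (window_ms / 1000.0)
    var = mu + mu**2 * gain_var
    cov = np.outer(mu, mu) * gain_var
    rho = cov / np.sqrt(np.outer(var, var))
    np.fill_diagonal(rho, 1.0)
    return rho


def simulate_population_counts(cfg: GainModelConfig) -> CountMatrix:
    rng = _rng(cfg.seed)
    rates = (np.full(cfg.n_units, 25.0) if cfg.rates_hz is None
             else np.asarray(cfg.rates_hz, dtype=float))
    if rates.size != cfg.n_units:
        raise ParameterError("rates_hz length must equal n_units")
    areas = list(cfg.areas) if cfg.areas is not None else ["V4"] * cfg.n_units
    mu = rates * (cfg.window_ms / 1000.0)
    if cfg.gain_var > 0:
        shape = 1.0 / cfg.gain_var
        g = rng.gamma(shape, scale=cfg.gain_var, size=cfg.n_trials)
    else:
        g = np.ones(cfg.n_trials)
    counts = rng.poisson(np.outer(g, mu)).astype(float)
    return CountMatrix(
        counts=counts, window_length_ms=cfg.window_ms, areas=areas,
        unit_ids=[f"u{i:03d}" for i in range(cfg.n_units)],
        meta={"generator": "gain_model", "rates_hz": rates,
              "gain_var": cfg.gain_var,
              "rho_true": gain_model_rho(rates, cfg.window_ms, cfg.gain_var),
              "seed": cfg.seed},
    )


# ---------------------------------------------------------------------------
# OU-modulated Poisson spike trains
# ---------------------------------------------------------------------------


@dataclass
class OUModelConfig:
    """Poisson spikes with rate lambda * (1 + m * x(t)), x an OU latent.

    x has stationary variance 1 and autocorrelation exp(-lag/tau_ms), so the
    shuffle-corrected spike-count autocorrelogram decays with the same time
    constant.  ``modulation`` must be < 1 to keep the rate positive (the
    rate is clipped at 0 regardless).
    """

    n_units: int = 1
    n_trials: int = 100
    rate_hz: float = 30.0
    modulation: float = 0.5
    tau_ms: float = 50.0
    window_ms: float = 200.0
    dt_ms: float = 1.0
    gain_var: float = 0.0  # optional shared trial gain on top of the OU latent
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation < 1.0:
            raise ParameterError("modulation must lie in [0, 1)")
        if self.tau_ms <= 0:
            raise ParameterError("tau_ms must be positive")
        if self.dt_ms <= 0 or self.dt_ms > self.tau_ms / 5:
            raise ParameterError("dt_ms must be positive and small relative to tau")


def _ou_paths(rng: np.random.Generator, n: int, n_bins: int, tau: float,
              dt: float) -> np.ndarray:
    """Exact discretization of a unit-variance OU process, shape (n, n_bins)."""
    from scipy.signal import lfilter

    a = math.exp(-dt / tau)
    innov = rng.standard_normal((n, n_bins)) * math.sqrt(1 - a * a)
    innov[:, 0] = rng.standard_normal(n)  # stationary start
    # AR(1) recursion x_k = a x_{k-1} + e_k as an IIR filter along time
    return lfilter([1.0], [1.0, -a], innov, axis=1)


def ou_binned_counts(cfg: OUModelConfig, rng: np.random.Generator,
                     n_bins: int, gains: Optional[np.ndarray] = None) -> np.ndarray:
    """Binned spike counts for all units/trials, shape (n_units, n_trials, n_bins)."""
    out = np.empty((cfg.n_units, cfg.n_trials, n_bins), dtype=np.int64)
    for u in range(cfg.n_units):
        x = _ou_paths(rng, cfg.n_trials, n_bins, cfg.tau_ms, cfg.dt_ms)
        rate = cfg.rate_hz * (1.0 + cfg.modulation * x)
        np.clip(rate, 0.0, None, out=rate)
        if gains is not None:
            rate = rate * gains[:, None]
        out[u] = rng.poisson(rate * (cfg.dt_ms / 1000.0))
    return out


def simulate_ou_spike_trains(cfg: OUModelConfig, *, areas: Optional[Sequence[str]] = None,
                             include_stimulus_window: bool = True) -> SpikeData:
    """Simulate OU-rate-modulated Poisson spike trains as a :class:`SpikeData`.

    The trial spans the 200 ms baseline-fixation window plus (optionally) a
    stimulus window of the same length; spikes are placed uniformly within
    their 1 ms bin.
    """
    rng = _rng(cfg.seed)
    span = cfg.window_ms * (2 if include_stimulus_window else 1)
    n_bins = int(round(span / cfg.dt_ms))
    gains = None
    if cfg.gain_var > 0:
        gains = rng.gamma(1.0 / cfg.gain_var, scale=cfg.gain_var, size=cfg.n_trials)
    counts = ou_binned_counts(cfg, rng, n_bins, gains)
    area_list = list(areas) if areas is not None else ["V4"] * cfg.n_units
    units = [(f"u{i:03d}", area_list[i]) for i in range(cfg.n_units)]
    spike_times: dict[str, list[np.ndarray]] = {}
    for u, (uid, _) in enumerate(units):
        trains = []
        for tr in range(cfg.n_trials):
            c = counts[u, tr]
            n_sp = int(c.sum())
            if n_sp == 0:
                trains.append(np.empty(0))
                continue
            bins = np.repeat(np.arange(n_bins), c)
            times = (bins + rng.random(n_sp)) * cfg.dt_ms
            trains.append(np.sort(times))
        spike_times[uid] = trains
    windows = {"baseline_fixation": (0.0, cfg.window_ms)}
    windows["stimulus"] = ((cfg.window_ms, 2 * cfg.window_ms)
                           if include_stimulus_window
                           else (cfg.window_ms, cfg.window_ms + 1.0))
    return SpikeData(units=units, spike_times=spike_times, windows=windows,
                     meta={"generator": "ou", "tau_ms": cfg.tau_ms,
                           "rate_hz": cfg.rate_hz, "modulation": cfg.modulation,
                           "gain_var": cfg.gain_var, "seed": cfg.seed})


# ---------------------------------------------------------------------------
# Tuned population responses to a color x shape grid
# ---------------------------------------------------------------------------


@dataclass
class TunedPopConfig:
    """Population with unimodal color/shape tuning and a disruption knob.

    ``disruption`` (d in [0, 1]) removes the across-population signal lying
    along the linear color and shape axes: that component of the mean
    response matrix is scaled by (1 - d) and replaced by isotropic trial
    noise of matched variance.  Signal orthogonal to the two feature axes
    (units' idiosyncratic nonlinear tuning) is untouched, so single-unit
    selectivity degrades far less than linear population decodability.
    """

    n_units: int = 40
    n_colors: int = 4
    n_shapes: int = 4
    n_repeats: int = 10
    noise_sd: float = 1.0
    disruption: float = 0.0
    tuning_amp: tuple[float, float] = (10.0, 30.0)
    tuning_width: tuple[float, float] = (0.8, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.disruption <= 1.0:
            raise ParameterError("disruption must lie in [0, 1]")


def simulate_tuned_responses(cfg: TunedPopConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Trial responses to every (color, shape) stimulus plus a stimulus table.

    Returns a float-valued :class:`CountMatrix` (trials x units, baseline
    window 200 ms) and a DataFrame with one row per trial: ``trial``,
    ``stimulus_id``, ``color``, ``shape``.
    """
    rng = _rng(cfg.seed)
    colors = np.arange(cfg.n_colors, dtype=float)
    shapes = np.arange(cfg.n_shapes, dtype=float)
    cc, ss = np.meshgrid(colors, shapes, indexing="ij")
    c_code, s_code = cc.ravel(), ss.ravel()
    n_stim = c_code.size

    pref_c = rng.uniform(0, cfg.n_colors - 1, cfg.n_units)
    pref_s = rng.uniform(0, cfg.n_shapes - 1, cfg.n_units)
    w_c = rng.uniform(*cfg.tuning_width, cfg.n_units)
    w_s = rng.uniform(*cfg.tuning_width, cfg.n_units)
    amp = rng.uniform(*cfg.tuning_amp, cfg.n_units)
    base = rng.uniform(2.0, 8.0, cfg.n_units)

    mean_resp = (base[None, :]
                 + amp[None, :]
                 * np.exp(-(c_code[:, None] - pref_c[None, :]) ** 2 / (2 * w_c**2))
                 * np.exp(-(s_code[:, None] - pref_s[None, :]) ** 2 / (2 * w_s**2)))

    # linear feature signal across the population: regress centered means on codes
    grand = mean_resp.mean(axis=0)
    centered = mean_resp - grand
    design = np.column_stack([c_code - c_code.mean(), s_code - s_code.mean()])
    beta, *_ = np.linalg.lstsq(design, centered, rcond=None)
    feature_signal = design @ beta
    d = cfg.disruption
    disrupted_mean = grand + (centered - feature_signal) + (1.0 - d) * feature_signal
    iso_sd = math.sqrt(d * feature_signal.var(axis=0).mean()) if d > 0 else 0.0

    stim_idx = np.tile(np.arange(n_stim), cfg.n_repeats)
    resp = disrupted_mean[stim_idx]
    if cfg.noise_sd > 0:
        resp = resp + rng.normal(0, cfg.noise_sd, resp.shape)
    if iso_sd > 0:
        resp = resp + rng.normal(0, iso_sd, resp.shape)
    np.clip(resp, 0.0, None, out=resp)

    stim_table = pd.DataFrame({
        "trial": np.arange(stim_idx.size),
        "stimulus_id": stim_idx,
        "color": c_code[stim_idx],
        "shape": s_code[stim_idx],
    })
    cm = CountMatrix(
        counts=resp, window_length_ms=200.0,
        areas=["V4"] * cfg.n_units,
        unit_ids=[f"u{i:03d}" for i in range(cfg.n_units)],
        meta={"generator": "tuned_pop", "disruption": d,
              "noise_sd": cfg.noise_sd, "seed": cfg.seed},
    )
    return cm, stim_table


# ---------------------------------------------------------------------------
# Longitudinal study
# ---------------------------------------------------------------------------

#: Healthy-baseline generator parameters at day 0 and their default per-day
#: drifts over the one-year study (300 testing days).  Signs mirror the
#: disease direction: inhibition failures and entropy increase, novelty
#: preference, shared variability and intrinsic timescale decrease.
STUDY_BASELINES = {
    "p_superfluous": 0.10,
    "structure": 0.85,
    "pref_novel": 0.75,
    "sigma2_gain": 0.02,
    "tau_ms": 45.0,
}
STUDY_SLOPES = {
    "p_superfluous": +0.001,
    "structure": -0.002,
    "pref_novel": -0.0006,
    "sigma2_gain": -5.0e-5,
    "tau_ms": -0.08,
}


def simulate_longitudinal_study(
    metric_slopes: Optional[dict[str, float]] = None,
    n_days: int = 300,
    sessions_per_day: int = 1,
    treatment: Optional[tuple[int, float]] = None,
    seed: int = 0,
    *,
    baselines: Optional[dict[str, float]] = None,
    day_step: int = 1,
    gap_trials: int = 60,
    foraging_trials: int = 60,
    pref_trials: int = 30,
    n_v4: int = 60,
    n_7a: int = 12,
    subject_id: str = "sim",
    with_spikes: bool = True,
) -> list[Session]:
    """Simulate a longitudinal study with linearly drifting generator parameters.

    Each testing day yields a gap, a foraging and a preferential session;
    the foraging session carries spike data from an OU-modulated,
    shared-gain Poisson population (V4 and 7a units) whose gain variance and
    timescale drift with the disease.  ``treatment=(start_day, effect)``
    adds ``effect`` to the foraging ``structure`` parameter from
    ``start_day`` onward (a positive effect partially restores organized
    foraging), while the underlying drift continues.

    Returns a flat list of :class:`Session`; each session's ``meta`` records
    the generator parameters used that day.
    """
    if n_days < 2:
        raise ParameterError("n_days must be >= 2")
    slopes = dict(STUDY_SLOPES)
    if metric_slopes:
        slopes.update(metric_slopes)
    base = dict(STUDY_BASELINES)
    if baselines:
        base.update(baselines)
    root = _rng(seed)
    sessions: list[Session] = []
    for di in range(n_days):
        day = di * day_step
        p = float(np.clip(base["p_superfluous"] + slopes["p_superfluous"] * day, 0, 1))
        s = base["structure"] + slopes["structure"] * day
        if treatment is not None and day >= treatment[0]:
            s += treatment[1]
        s = float(np.clip(s, 0, 1))
        pref = float(np.clip(base["pref_novel"] + slopes["pref_novel"] * day, 0, 1))
        sig2 = float(max(base["sigma2_gain"] + slopes["sigma2_gain"] * day, 1e-4))
        tau = float(max(base["tau_ms"] + slopes["tau_ms"] * day, 6.0))
        for rep in range(sessions_per_day):
            seeds = root.integers(0, 2**31 - 1, size=5)
            tag = f"{day}" if sessions_per_day == 1 else f"{day}.{rep}"
            treated = treatment is not None and day >= treatment[0]
            g = simulate_gap_session(p, n_trials=gap_trials, seed=int(seeds[0]),
                                     day=day, subject_id=subject_id,
                                     session_id=f"gap-{subject_id}-d{tag}")
            f = simulate_foraging_session(
                ForagingSimConfig(n_trials=foraging_trials, structure=s,
                                  seed=int(seeds[1])),
                day=day, subject_id=subject_id,
                session_id=f"foraging-{subject_id}-d{tag}")
            f.meta.update({"sigma2_gain": sig2, "tau_ms": tau})
            if with_spikes:
                rates = _rng(int(seeds[4])).uniform(12.0, 45.0, n_v4 + n_7a)
                f.spikes = _study_spikes(
                    n_v4=n_v4, n_7a=n_7a, n_trials=len(f.trials),
                    rates_hz=rates, tau_ms=tau, gain_var=sig2,
                    seed=int(seeds[2]))
            pr = simulate_preferential_session(
                pref, n_trials=pref_trials, seed=int(seeds[3]), day=day,
                subject_id=subject_id, session_id=f"pref-{subject_id}-d{tag}")
            for sess in (g, f, pr):
                sess.treatment_flag = treated
                sess.meta["study_day"] = day
                sessions.append(sess)
    return sessions


def _study_spikes(n_v4: int, n_7a: int, n_trials: int, rates_hz: np.ndarray,
                  tau_ms: float, gain_var: float, seed: int,
                  modulation: float = 0.6, window_ms: float = 200.0) -> SpikeData:
    """OU-modulated, shared-gain Poisson population for one study day.

    A gamma trial gain (variance ``gain_var``) shared by every unit induces
    noise correlations; independent OU latents with timescale ``tau_ms``
    shape each unit's autocorrelogram.  The shuffle-corrected
    autocorrelogram's exponential decay still has time constant tau: the
    static gain only adds a lag-independent offset, which the fit's constant
    term absorbs.
    """
    rng = _rng(seed)
    n_units = n_v4 + n_7a
    n_bins = int(round(2 * window_ms))  # baseline + stimulus epochs at 1 ms
    gains = (rng.gamma(1.0 / gain_var, scale=gain_var, size=n_trials)
             if gain_var > 0 else np.ones(n_trials))
    units = [(f"u{i:03d}", "V4" if i < n_v4 else "7a") for i in range(n_units)]
    spike_times: dict[str, list[np.ndarray]] = {}
    for i, (uid, _) in enumerate(units):
        x = _ou_paths(rng, n_trials, n_bins, tau_ms, 1.0)
        rate = rates_hz[i] * (1.0 + modulation * x)
        np.clip(rate, 0.0, None, out=rate)
        rate *= gains[:, None]
        rate[:, int(window_ms):] *= 1.5  # visually evoked response in the stimulus epoch
        counts = rng.poisson(rate / 1000.0)
        trains = []
        for tr in range(n_trials):
            c = counts[tr]
            n_sp = int(c.sum())
            if n_sp == 0:
                trains.append(np.empty(0))
                continue
            bins = np.repeat(np.arange(n_bins), c)
            trains.append(np.sort(bins + rng.random(n_sp)))
        spike_times[uid] = trains
    return SpikeData(
        units=units, spike_times=spike_times,
        windows={"baseline_fixation": (0.0, window_ms),
                 "stimulus": (window_ms, 2 * window_ms)},
        meta={"generator": "study_spikes", "tau_ms": tau_ms,
              "gain_var": gain_var, "rates_hz": rates_hz,
              "modulation": modulation, "seed": seed},
    )
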