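"""Per-session behavioral disorganization metrics.

Three visually guided tasks are scored:

* **gap** — rate of superfluous saccades launched between fixation-spot
  offset and target onset (a failure of behavioral inhibition);
* **foraging** — reward per fixation, mean distance between consecutive
  fixations, revisit rate, and the transition-entropy statistic: the
  Shannon entropy of the fixation-location transition probabilities,
  z-scored against a within-trial shuffle null (negative z = more
  structured than chance, near zero = approximately random foraging);
* **preferential** — novelty preference (fraction of image-viewing time on
  the novel image), image-to-image switches per trial, and fixation
  durations per image class.

Conventions for the entropy statistic (configurable where noted):
consecutive same-location fixations are collapsed into single visits before
transitions are counted; fixations near no stimulus ("elsewhere") break the
transition chain rather than bridging it; transitions are pooled across
trials within a session; entropy is the sum of row entropies of the
row-conditional transition matrix ("row-sum"), with an occupancy-weighted
entropy rate available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .core_data import ELSEWHERE, Session, Trial
from .errors import ParameterError, SessionExcludedError, UndefinedMetricError, ValidationError

#: Landing points farther than this from the fixation spot count as having
#: left the fixation window (the task's 1.0 degree circular window).
FIXATION_WINDOW_DEG = 1.0

#: Minimum completed trials for a session to enter the entropy analysis.
MIN_ENTROPY_TRIALS = 20


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class TransitionMatrix:
    """Pooled fixation-location transition counts and row-conditional probabilities."""

    p: np.ndarray          # (K, K); rows with no transitions are all-zero
    counts: np.ndarray     # (K, K) raw transition counts, zero diagonal
    occupancy: np.ndarray  # (K,) visit counts per location
    location_ids: np.ndarray

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())


@dataclass
class EntropyResult:
    """Transition entropy with its within-trial shuffle null."""

    H: float
    mu_shuffled: float
    sigma_shuffled: float
    z: float  # NaN when the null has zero spread
    n_shuffles: int
    n_transitions: int
    convention: str = "row-sum"

    @property
    def defined(self) -> bool:
        return math.isfinite(self.z)


class ForagingMetrics(NamedTuple):
    reward_per_fixation: float
    mean_interfix_distance_deg: float
    revisit_rate: float


class PreferentialMetrics(NamedTuple):
    novelty_preference: float
    switches_per_trial: float
    fixation_duration_ms: dict  # {"novel": ..., "familiar": ...}


# ---------------------------------------------------------------------------
# Gap task
# ---------------------------------------------------------------------------


def superfluous_saccade_rate(session: Session) -> float:
    """Fraction of completed gap trials with a saccade leaving the fixation
    window strictly inside the (fixation-spot offset, target onset) gap.

    A saccade counts only if its landing point lies more than 1.0 degree
    from the fixation spot; small corrective movements within the window do
    not.
    """
    if session.task != "gap":
        raise ParameterError(f"superfluous_saccade_rate needs a gap session, got {session.task!r}")
    trials = session.completed_trials()
    if not trials:
        raise UndefinedMetricError("no completed trials")
    n_super = 0
    for t in trials:
        off = t.timing["fixation_spot_offset"]
        on = t.timing["target_onset"]
        spot = next((it for it in t.layout if it.role == "fixation_spot"), None)
        sx, sy = (spot.x, spot.y) if spot is not None else (0.0, 0.0)
        for s in t.saccades:
            if off < s.onset < on and math.hypot(s.landing_x - sx,
                                                 s.landing_y - sy) > FIXATION_WINDOW_DEG:
                n_super += 1
                break
    return n_super / len(trials)


# ---------------------------------------------------------------------------
# Foraging scan-path metrics
# ---------------------------------------------------------------------------


def _require_assigned(trial: Trial) -> None:
    if any(f.location_id is None for f in trial.fixations):
        raise ValidationError(
            f"trial {trial.trial_id}: fixations lack location assignment; "
            "run assign_locations first")


def _visit_sequence(trial: Trial) -> np.ndarray:
    """Collapse consecutive same-location fixations into visits.

    Keeps ELSEWHERE entries (they break transition chains downstream)."""
    _require_assigned(trial)
    locs = [f.location_id for f in trial.fixations]
    out = []
    for k in locs:
        if not out or out[-1] != k:
            out.append(k)
    return np.asarray(out, dtype=np.int64)


def foraging_metrics(session: Session) -> ForagingMetrics:
    """Reward per fixation, mean inter-fixation distance, and revisit rate.

    Distances are measured between consecutive *visits* (consecutive
    fixations at the same location collapse into one, since no saccade
    separates them); a visit takes the position of its first fixation.
    """
    if session.task != "foraging":
        raise ParameterError(f"foraging_metrics needs a foraging session, got {session.task!r}")
    trials = session.completed_trials()
    n_rewarded = 0
    n_on_stim = 0
    dists: list[float] = []
    n_visits = 0
    n_revisits = 0
    for t in trials:
        _require_assigned(t)
        n_rewarded += len(t.rewarded_fixation_ids)
        n_on_stim += sum(1 for f in t.fixations if f.location_id != ELSEWHERE)
        visit_pos = [(f.x, f.y) for prev, f in zip([None] + list(t.fixations),
                                                   t.fixations)
                     if prev is None or f.location_id != prev.location_id]
        for (ax, ay), (bx, by) in zip(visit_pos, visit_pos[1:]):
            dists.append(math.hypot(bx - ax, by - ay))
        seen: set[int] = set()
        for k in _visit_sequence(t):
            if k == ELSEWHERE:
                continue
            n_visits += 1
            if k in seen:
                n_revisits += 1
            seen.add(int(k))
    if n_on_stim == 0 or n_visits == 0:
        raise UndefinedMetricError("no on-stimulus fixations in session")
    return ForagingMetrics(
        reward_per_fixation=n_rewarded / n_on_stim,
        mean_interfix_distance_deg=float(np.mean(dists)) if dists else float("nan"),
        revisit_rate=n_revisits / n_visits,
    )


# ---------------------------------------------------------------------------
# Preferential looking
# ---------------------------------------------------------------------------


def preferential_metrics(session: Session) -> PreferentialMetrics:
    """Novelty preference, switches per trial, and per-class fixation durations.

    Novelty preference is the novel fraction of total image-dwell time
    pooled over trials; a switch is a consecutive fixation pair on the two
    different image regions; fixations on neither image are excluded from
    the duration averages and break switch adjacency.
    """
    if session.task != "preferential":
        raise ParameterError(
            f"preferential_metrics needs a preferential session, got {session.task!r}")
    trials = session.completed_trials()
    dwell = {"novel": 0.0, "familiar": 0.0}
    durs: dict[str, list[float]] = {"novel": [], "familiar": []}
    total_switches = 0
    for t in trials:
        _require_assigned(t)
        role_of = {it.location_id: it.role for it in t.layout}
        classes = []
        for f in t.fixations:
            role = role_of.get(f.location_id)
            if role == "novel_image":
                cls = "novel"
            elif role == "familiar_image":
                cls = "familiar"
            else:
                cls = None
            classes.append(cls)
            if cls is not None:
                dwell[cls] += f.duration
                durs[cls].append(f.duration)
        for a, b in zip(classes, classes[1:]):
            if a is not None and b is not None and a != b:
                total_switches += 1
    total = dwell["novel"] + dwell["familiar"]
    if total <= 0 or not trials:
        raise UndefinedMetricError("no image-dwell time in session")
    return PreferentialMetrics(
        novelty_preference=dwell["novel"] / total,
        switches_per_trial=total_switches / len(trials),
        fixation_duration_ms={
            cls: (float(np.mean(v)) if v else float("nan")) for cls, v in durs.items()
        },
    )


# ---------------------------------------------------------------------------
# Transition entropy
# ---------------------------------------------------------------------------


def _session_visits(session: Session, min_completed: int) -> tuple[list[np.ndarray], int]:
    if session.task != "foraging":
        raise ParameterError(f"transition entropy needs a foraging session, got {session.task!r}")
    trials = session.completed_trials()
    if len(trials) < min_completed:
        raise SessionExcludedError(
            f"session {session.session_id}: {len(trials)} completed trials "
            f"< required {min_completed}")
    n_locs = 1 + max((it.location_id for t in trials for it in t.layout), default=-1)
    if n_locs < 2:
        raise UndefinedMetricError("layout has < 2 locations")
    return [_visit_sequence(t) for t in trials], n_locs


def _pair_codes(visits: np.ndarray, k: int) -> np.ndarray:
    """Codes i*k + j for consecutive visit pairs with both ends on-stimulus
    and i != j (self-pairs arise only after shuffling and correspond to
    collapsed visits)."""
    if visits.size < 2:
        return np.empty(0, dtype=np.int64)
    a, b = visits[:-1], visits[1:]
    ok = (a != b) & (a != ELSEWHERE) & (b != ELSEWHERE)
    return a[ok] * k + b[ok]


def _entropy_from_counts(counts: np.ndarray, k: int, convention: str) -> float:
    counts = counts.reshape(k, k).astype(float)
    row_sums = counts.sum(axis=1)
    rows = row_sums > 0
    if not np.any(rows):
        return 0.0
    p = counts[rows] / row_sums[rows, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    row_h = -plogp.sum(axis=1)
    if convention == "row-sum":
        return float(row_h.sum())
    if convention == "rate":
        w = row_sums[rows] / row_sums.sum()
        return float((w * row_h).sum())
    raise ParameterError(f"unknown entropy convention {convention!r}")


def _constrained_perms(visits: np.ndarray, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """``n`` random within-trial orders of ``visits`` without adjacent
    duplicates, shape (n, len(visits)).

    A collapsed visit sequence never repeats a location back-to-back, so
    the shuffle null samples uniformly from permutations respecting that
    constraint (rejection sampling; the observed order shows at least one
    exists).  If valid orders are too rare to fill the request, the ones
    found are resampled with replacement.
    """
    L = visits.size
    if L < 2 or np.unique(visits).size == L:
        # all-distinct (or trivial): every permutation is valid
        keys = rng.random((n, L))
        return visits[np.argsort(keys, axis=1)]
    found: list[np.ndarray] = []
    for _ in range(60):
        batch = visits[np.argsort(rng.random((2 * n, L)), axis=1)]
        good = batch[~np.any(batch[:, 1:] == batch[:, :-1], axis=1)]
        if good.size:
            found.append(good)
        if sum(f.shape[0] for f in found) >= n:
            break
    if not found:
        return np.tile(visits, (n, 1))  # degenerate multiset: keep observed order
    pool = np.concatenate(found, axis=0)
    if pool.shape[0] >= n:
        return pool[:n]
    return pool[rng.integers(pool.shape[0], size=n)]


def transition_matrix(session: Session, *, min_completed: int = MIN_ENTROPY_TRIALS) -> TransitionMatrix:
    """Pooled fixation-location transition matrix for a foraging session.

    Consecutive same-location fixations are collapsed into visits,
    transitions involving off-stimulus ("elsewhere") visits are dropped,
    and counts are pooled across completed trials before row normalization.
    Sessions with fewer than ``min_completed`` completed trials are
    excluded.
    """
    visit_lists, k = _session_visits(session, min_completed)
    counts = np.zeros(k * k, dtype=np.int64)
    occupancy = np.zeros(k, dtype=np.int64)
    distinct: set[int] = set()
    for v in visit_lists:
        on = v[v != ELSEWHERE]
        occupancy += np.bincount(on, minlength=k)
        distinct.update(int(x) for x in on)
        codes = _pair_codes(v, k)
        if codes.size:
            counts += np.bincount(codes, minlength=k * k)
    if len(distinct) < 2:
        raise UndefinedMetricError("fewer than 2 distinct visited locations")
    cm = counts.reshape(k, k).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row_sums > 0, cm / row_sums, 0.0)
    return TransitionMatrix(p=p, counts=cm.astype(np.int64), occupancy=occupancy,
                            location_ids=np.arange(k))


def transition_entropy(tm: TransitionMatrix, convention: str = "row-sum") -> float:
    """Shannon entropy of the transition distribution, in bits.

    ``row-sum`` sums the entropy of every observed row's conditional
    distribution (H = -sum_ij p_ij log2 p_ij over rows); ``rate`` weights
    rows by their occupancy, giving an entropy rate in bits per transition.
    H = 0 exactly iff every observed row is deterministic.
    """
    k = tm.counts.shape[0]
    return _entropy_from_counts(tm.counts.astype(float).ravel(), k, convention)


def entropy_zscore(session: Session, n_shuffles: int = 1000,
                   seed: Optional[int] = 0, *,
                   convention: str = "row-sum",
                   min_completed: int = MIN_ENTROPY_TRIALS) -> EntropyResult:
    """Transition entropy z-scored against a within-trial shuffle null.

    The null permutes the visit order independently within every trial,
    rebuilds the pooled transition matrix and recomputes H; the z-score is
    (H_actual - mu_shuffled) / sigma_shuffled.  Negative values indicate
    more structured behavior than expected by chance; values near zero
    indicate approximately random foraging.  When the null distribution has
    zero spread (e.g. a session with a single pair of visits) the z-score
    is undefined and returned as NaN alongside H and the null moments.
    """
    if n_shuffles < 2:
        raise ParameterError("need at least 2 shuffles")
    visit_lists, k = _session_visits(session, min_completed)
    rng = np.random.default_rng(seed)

    actual_counts = np.zeros(k * k, dtype=np.int64)
    distinct: set[int] = set()
    for v in visit_lists:
        distinct.update(int(x) for x in v[v != ELSEWHERE])
        codes = _pair_codes(v, k)
        if codes.size:
            actual_counts += np.bincount(codes, minlength=k * k)
    if len(distinct) < 2:
        raise UndefinedMetricError("fewer than 2 distinct visited locations")
    h_actual = _entropy_from_counts(actual_counts, k, convention)
    n_transitions = int(actual_counts.sum())

    # Null: permute visits within every trial, restricted to orders without
    # adjacent duplicates (a visit sequence cannot self-transition, so
    # unconstrained permutation would shrink the null's transition count
    # and bias z upward).
    shuffled = np.concatenate(
        [_constrained_perms(v, n_shuffles, rng) for v in visit_lists], axis=1)
    trial_ix = np.concatenate([np.full(v.size, i) for i, v in enumerate(visit_lists)])
    same_trial = trial_ix[1:] == trial_ix[:-1]
    h_null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        v = shuffled[s]
        a, b = v[:-1], v[1:]
        ok = same_trial & (a != b) & (a != ELSEWHERE) & (b != ELSEWHERE)
        codes = a[ok] * k + b[ok]
        counts = np.bincount(codes, minlength=k * k)
        h_null[s] = _entropy_from_counts(counts, k, convention)

    mu = float(h_null.mean())
    sigma = float(h_null.std(ddof=0))
    z = (h_actual - mu) / sigma if sigma > 0 else float("nan")
    return EntropyResult(H=h_actual, mu_shuffled=mu, sigma_shuffled=sigma, z=z,
                         n_shuffles=n_shuffles, n_transitions=n_transitions,
                         convention=convention)
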