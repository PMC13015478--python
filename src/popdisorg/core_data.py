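"""Domain types, session bundle I/O, and fixation-to-location assignment.

Conventions
-----------
* Positions are in degrees of visual angle, screen-centered, x rightward,
  y upward.
* All times are milliseconds relative to trial start.
* A session is one experimental day: a block of trials of a single task,
  optionally with simultaneously recorded spike data, and a signed ``day``
  index relative to disease onset (day 0 = induction).

Serialized form ("popdisorg-session/1")
---------------------------------------
``json_bundle``
    A single JSON file holding metadata, trials and (optionally) spikes.
``parquet_bundle``
    A directory with ``session.json`` (everything except spike times) and
    ``spikes.parquet`` (columns ``unit_id, area, trial_index, time_ms``),
    for sessions whose spike tables are too large to keep in JSON.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError, SchemaError, ValidationError

SCHEMA_VERSION = "popdisorg-session/1"

#: Sentinel location id for fixations that land near no layout item.
ELSEWHERE = -1

#: Layout roles understood by the analyses.
ROLES = {
    "target",
    "distractor",
    "novel_image",
    "familiar_image",
    "fixation_spot",
    "saccade_target",
}

TASKS = {"gap", "foraging", "preferential"}

#: Required length of the pre-stimulus stable-fixation window (ms).
BASELINE_WINDOW_MS = 200.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixationEvent:
    """A single fixation: on/offset in ms, gaze position in degrees.

    ``location_id`` is assigned by :func:`assign_locations`; ``None`` means
    unassigned, :data:`ELSEWHERE` means assigned but near no layout item.
    """

    onset: float
    offset: float
    x: float
    y: float
    location_id: Optional[int] = None

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def __post_init__(self) -> None:
        if not (self.offset > self.onset):
            raise ValidationError(
                f"fixation offset ({self.offset}) must exceed onset ({self.onset})"
            )


@dataclass(frozen=True)
class SaccadeEvent:
    """A saccade: onset time and landing position."""

    onset: float
    landing_x: float
    landing_y: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.onset):
            raise ValidationError("saccade onset must be finite")


@dataclass(frozen=True)
class LayoutItem:
    """One discrete display location with its role in the task."""

    location_id: int
    x: float
    y: float
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown layout role {self.role!r}")


@dataclass
class Trial:
    """One behavioral trial with its events, display layout and timing marks.

    ``timing`` holds task-specific marks (ms): gap trials require
    ``fixation_spot_offset`` and ``target_onset``; preferential trials
    require ``image_onset``.  ``rewarded_fixation_ids`` indexes into
    ``fixations``.
    """

    trial_id: int
    task: str
    fixations: list[FixationEvent] = field(default_factory=list)
    saccades: list[SaccadeEvent] = field(default_factory=list)
    layout: list[LayoutItem] = field(default_factory=list)
    timing: dict[str, float] = field(default_factory=dict)
    rewarded_fixation_ids: set[int] = field(default_factory=set)
    completed: bool = True


@dataclass
class SpikeData:
    """Spike times per unit per trial, with area labels and named windows.

    ``spike_times[unit_id]`` is a list (one entry per trial, aligned with
    ``Session.trials``) of arrays of spike times in ms relative to trial
    start.  ``windows`` must include ``baseline_fixation`` (length 200 ms,
    the pre-stimulus stable-fixation epoch) and ``stimulus``.
    """

    units: list[tuple[str, str]]  # (unit_id, area), area in {"V4", "7a"}
    spike_times: dict[str, list[np.ndarray]]
    windows: dict[str, tuple[float, float]]
    meta: dict = field(default_factory=dict)
    _count_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def unit_ids(self) -> list[str]:
        return [u for u, _ in self.units]

    @property
    def areas(self) -> dict[str, str]:
        return dict(self.units)

    def n_trials(self) -> int:
        return len(next(iter(self.spike_times.values()))) if self.spike_times else 0

    def counts_in_window(self, window: str = "baseline_fixation") -> "CountMatrix":
        """Bin spikes into a trials x units count matrix for a named window.

        Results are cached per window name (spike times are treated as
        immutable once attached to a session)."""
        if window in self._count_cache:
            return self._count_cache[window]
        if window not in self.windows:
            raise ParameterError(f"unknown window {window!r}")
        lo, hi = self.windows[window]
        ids = self.unit_ids
        n_tr = self.n_trials()
        counts = np.zeros((n_tr, len(ids)))
        for j, uid in enumerate(ids):
            for i, st in enumerate(self.spike_times[uid]):
                counts[i, j] = np.count_nonzero((st >= lo) & (st < hi))
        cm = CountMatrix(
            counts=counts,
            window_length_ms=hi - lo,
            areas=[self.areas[u] for u in ids],
            unit_ids=list(ids),
        )
        self._count_cache[window] = cm
        return cm


@dataclass
class CountMatrix:
    """Trial-by-unit spike counts in a fixed analysis window.

    ``counts`` may be float-valued when produced by a rate-model generator;
    spike-derived matrices are integer.  ``meta`` carries generator ground
    truth when the matrix is synthetic.
    """

    counts: np.ndarray  # (n_trials, n_units), >= 0
    window_length_ms: float
    areas: list[str]
    unit_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D trials x units array")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts must be finite and non-negative")
        if self.window_length_ms <= 0:
            raise ValidationError("window length must be positive")
        if len(self.areas) != self.counts.shape[1] or len(self.unit_ids) != self.counts.shape[1]:
            raise ValidationError("areas / unit_ids must match the unit dimension")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    def rates_hz(self) -> np.ndarray:
        """Mean firing rate per unit in spikes/s."""
        return self.counts.mean(axis=0) / (self.window_length_ms / 1000.0)


@dataclass
class Session:
    """One experimental day: trials of a single task plus optional spikes."""

    session_id: str
    day: int
    subject_id: str
    trials: list[Trial]
    spikes: Optional[SpikeData] = None
    treatment_flag: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def task(self) -> str:
        return self.trials[0].task if self.trials else ""

    def completed_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.completed]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_trial(trial: Trial) -> None:
    if trial.task not in TASKS:
        raise SchemaError(f"trial {trial.trial_id}: unknown task {trial.task!r}")
    onsets = [f.onset for f in trial.fixations]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValidationError(f"trial {trial.trial_id}: fixation onsets not time-ordered")
    s_onsets = [s.onset for s in trial.saccades]
    if any(b < a for a, b in zip(s_onsets, s_onsets[1:])):
        raise ValidationError(f"trial {trial.trial_id}: saccade onsets not time-ordered")
    if trial.task == "gap":
        for key in ("fixation_spot_offset", "target_onset"):
            if key not in trial.timing:
                raise SchemaError(
                    f"trial {trial.trial_id}: gap trial missing timing mark {key!r}"
                )
    if trial.task == "preferential":
        roles = [it.role for it in trial.layout]
        if roles.count("novel_image") != 1 or roles.count("familiar_image") != 1:
            raise ValidationError(
                f"trial {trial.trial_id}: preferential trial must have exactly one "
                "novel and one familiar image region"
            )
    n_fix = len(trial.fixations)
    if any(i < 0 or i >= n_fix for i in trial.rewarded_fixation_ids):
        raise ValidationError(f"trial {trial.trial_id}: rewarded fixation index out of range")


def validate_session(session: Session) -> None:
    if not session.trials:
        raise ValidationError("session must contain at least one trial")
    tasks = {t.task for t in session.trials}
    if len(tasks) > 1:
        raise ValidationError(f"session mixes tasks {sorted(tasks)}; one task per session")
    for t in session.trials:
        validate_trial(t)
    if session.spikes is not None:
        sp = session.spikes
        if "baseline_fixation" not in sp.windows or "stimulus" not in sp.windows:
            raise SchemaError("spike data must define 'baseline_fixation' and 'stimulus' windows")
        lo, hi = sp.windows["baseline_fixation"]
        if abs((hi - lo) - BASELINE_WINDOW_MS) > 1e-6:
            raise ValidationError(
                f"baseline_fixation window must be {BASELINE_WINDOW_MS:g} ms long, got {hi - lo:g}"
            )
        n_tr = len(session.trials)
        for uid, trains in sp.spike_times.items():
            if len(trains) != n_tr:
                raise ValidationError(
                    f"unit {uid}: {len(trains)} spike trains for {n_tr} trials"
                )
            for arr in trains:
                a = np.asarray(arr)
                if a.size and (not np.all(np.isfinite(a)) or np.any(a < 0)):
                    raise ValidationError(f"unit {uid}: spike times must be finite and >= 0")


# ---------------------------------------------------------------------------
# Location assignment
# ---------------------------------------------------------------------------


def assign_locations(trial: Trial, radius: float = 2.0) -> Trial:
    """Assign each fixation to the nearest layout item within ``radius`` degrees.

    Fixations farther than ``radius`` from every layout item get the
    :data:`ELSEWHERE` sentinel instead of being dropped, so downstream
    metrics can choose their own handling.  Ties (two items equidistant
    within the radius) are broken by the lowest ``location_id``.  The
    operation is idempotent and returns a new :class:`Trial`.
    """
    if radius <= 0:
        raise ParameterError(f"radius must be positive, got {radius}")
    if not trial.layout:
        raise ValidationError(f"trial {trial.trial_id}: cannot assign with empty layout")
    items = sorted(trial.layout, key=lambda it: it.location_id)
    xy = np.array([[it.x, it.y] for it in items])
    ids = np.array([it.location_id for it in items])
    new_fix = []
    for f in trial.fixations:
        d = np.hypot(xy[:, 0] - f.x, xy[:, 1] - f.y)
        within = d <= radius
        if np.any(within):
            # argmin over sorted-by-id items -> lowest id wins exact ties
            k = int(np.argmin(np.where(within, d, np.inf)))
            loc = int(ids[k])
        else:
            loc = ELSEWHERE
        new_fix.append(replace(f, location_id=loc))
    return replace(trial, fixations=new_fix)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays so ``json.dump`` accepts them."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _trial_to_dict(t: Trial) -> dict:
    return {
        "trial_id": t.trial_id,
        "task": t.task,
        "completed": t.completed,
        "timing": dict(t.timing),
        "rewarded_fixation_ids": sorted(t.rewarded_fixation_ids),
        "layout": [
            {"location_id": it.location_id, "x": it.x, "y": it.y, "role": it.role}
            for it in t.layout
        ],
        "fixations": [
            {"onset": f.onset, "offset": f.offset, "x": f.x, "y": f.y,
             "location_id": f.location_id}
            for f in t.fixations
        ],
        "saccades": [
            {"onset": s.onset, "landing_x": s.landing_x, "landing_y": s.landing_y}
            for s in t.saccades
        ],
    }


def _trial_from_dict(d: dict) -> Trial:
    try:
        return Trial(
            trial_id=int(d["trial_id"]),
            task=d["task"],
            completed=bool(d["completed"]),
            timing={k: float(v) for k, v in d["timing"].items()},
            rewarded_fixation_ids=set(d["rewarded_fixation_ids"]),
            layout=[LayoutItem(int(it["location_id"]), float(it["x"]), float(it["y"]),
                               it["role"]) for it in d["layout"]],
            fixations=[FixationEvent(float(f["onset"]), float(f["offset"]),
                                     float(f["x"]), float(f["y"]),
                                     None if f["location_id"] is None else int(f["location_id"]))
                       for f in d["fixations"]],
            saccades=[SaccadeEvent(float(s["onset"]), float(s["landing_x"]),
                                   float(s["landing_y"])) for s in d["saccades"]],
        )
    except KeyError as e:
        raise SchemaError(f"trial record missing field {e.args[0]!r}") from e


def _session_header(session: Session) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "session_id": session.session_id,
        "subject_id": session.subject_id,
        "day": session.day,
        "treatment_flag": session.treatment_flag,
        "meta": _jsonable(session.meta),
        "trials": [_trial_to_dict(t) for t in session.trials],
    }


def _spikes_to_dict(sp: SpikeData) -> dict:
    return {
        "units": [{"unit_id": u, "area": a} for u, a in sp.units],
        "windows": {k: [v[0], v[1]] for k, v in sp.windows.items()},
        "spike_times": {u: [np.asarray(a, dtype=float).tolist() for a in trains]
                        for u, trains in sp.spike_times.items()},
        "meta": _jsonable(sp.meta),
    }


def _spikes_from_dict(d: dict) -> SpikeData:
    return SpikeData(
        units=[(u["unit_id"], u["area"]) for u in d["units"]],
        windows={k: (float(v[0]), float(v[1])) for k, v in d["windows"].items()},
        spike_times={u: [np.asarray(a, dtype=float) for a in trains]
                     for u, trains in d["spike_times"].items()},
        meta=d.get("meta", {}),
    )


def write_session(session: Session, path: str, format: str = "json_bundle") -> None:
    """Write a validated session bundle.

    ``json_bundle`` writes a single JSON file; ``parquet_bundle`` writes a
    directory with ``session.json`` and a columnar ``spikes.parquet`` table.
    Output is byte-stable for a given session (fixed field order, no
    timestamps), so reruns produce identical files.
    """
    validate_session(session)
    if format == "json_bundle":
        doc = _session_header(session)
        if session.spikes is not None:
            doc["spikes"] = _spikes_to_dict(session.spikes)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    elif format == "parquet_bundle":
        import pyarrow as pa
        import pyarrow.parquet as pq

        os.makedirs(path, exist_ok=True)
        doc = _session_header(session)
        if session.spikes is not None:
            sp = session.spikes
            doc["spike_units"] = [{"unit_id": u, "area": a} for u, a in sp.units]
            doc["spike_windows"] = {k: [v[0], v[1]] for k, v in sp.windows.items()}
            uid_col, area_col, tr_col, t_col = [], [], [], []
            areas = sp.areas
            for u, trains in sp.spike_times.items():
                for i, arr in enumerate(trains):
                    arr = np.asarray(arr, dtype=float)
                    uid_col.extend([u] * arr.size)
                    area_col.extend([areas[u]] * arr.size)
                    tr_col.extend([i] * arr.size)
                    t_col.extend(arr.tolist())
            table = pa.table({
                "unit_id": pa.array(uid_col, type=pa.string()),
                "area": pa.array(area_col, type=pa.string()),
                "trial_index": pa.array(tr_col, type=pa.int32()),
                "time_ms": pa.array(t_col, type=pa.float64()),
            })
            pq.write_table(table, os.path.join(path, "spikes.parquet"))
        with open(os.path.join(path, "session.json"), "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        raise ParameterError(f"unknown format {format!r}")


def read_session(path: str, format: str = "json_bundle") -> Session:
    """Read and validate a session bundle written by :func:`write_session`."""
    if format == "json_bundle":
        if not os.path.exists(path):
            raise SchemaError(f"no such session bundle: {path}")
        with open(path) as fh:
            doc = json.load(fh)
        spikes = _spikes_from_dict(doc["spikes"]) if "spikes" in doc else None
    elif format == "parquet_bundle":
        meta_path = os.path.join(path, "session.json")
        if not os.path.exists(meta_path):
            raise SchemaError(f"no session.json under {path}")
        with open(meta_path) as fh:
            doc = json.load(fh)
        spikes = None
        spk_path = os.path.join(path, "spikes.parquet")
        if "spike_units" in doc:
            import pyarrow.parquet as pq

            table = pq.read_table(spk_path).to_pandas()
            n_tr = len(doc["trials"])
            spike_times: dict[str, list[np.ndarray]] = {}
            units = [(u["unit_id"], u["area"]) for u in doc["spike_units"]]
            for u, _ in units:
                sub = table[table.unit_id == u]
                spike_times[u] = [
                    np.sort(sub.time_ms[sub.trial_index == i].to_numpy())
                    for i in range(n_tr)
                ]
            spikes = SpikeData(
                units=units,
                windows={k: (float(v[0]), float(v[1]))
                         for k, v in doc["spike_windows"].items()},
                spike_times=spike_times,
            )
    else:
        raise ParameterError(f"unknown format {format!r}")

    if doc.get("schema") != SCHEMA_VERSION:
        raise SchemaError(f"unrecognized schema version {doc.get('schema')!r}")
    try:
        session = Session(
            session_id=doc["session_id"],
            subject_id=doc["subject_id"],
            day=int(doc["day"]),
            treatment_flag=bool(doc["treatment_flag"]),
            meta=doc.get("meta", {}),
            trials=[_trial_from_dict(t) for t in doc["trials"]],
            spikes=spikes,
        )
    except KeyError as e:
        raise SchemaError(f"session bundle missing field {e.args[0]!r}") from e
    validate_session(session)
    return session
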