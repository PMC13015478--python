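"""Shared fixtures: small hand-built sessions with known metric values."""

import numpy as np
import pytest

from popdisorg.core_data import (
    FixationEvent,
    LayoutItem,
    SaccadeEvent,
    Session,
    SpikeData,
    Trial,
)


def make_gap_trial(trial_id, saccades, fix_off=500.0, target_onset=700.0,
                   completed=True):
    layout = [LayoutItem(0, 0.0, 0.0, "fixation_spot"),
              LayoutItem(1, 8.0, 0.0, "saccade_target")]
    fixations = [FixationEvent(0.0, fix_off, 0.0, 0.0, 0),
                 FixationEvent(target_onset + 200, target_onset + 500, 8.0, 0.0, 1)]
    return Trial(trial_id=trial_id, task="gap", fixations=fixations,
                 saccades=saccades, layout=layout,
                 timing={"fixation_spot_offset": fix_off,
                         "target_onset": target_onset},
                 rewarded_fixation_ids={1}, completed=completed)


def make_foraging_trial(trial_id, locations, layout=None, positions=None,
                        rewarded=frozenset()):
    """Trial whose fixations visit ``locations`` in order.

    Positions default to the layout centers of the visited locations."""
    if layout is None:
        layout = [LayoutItem(k, 5.0 * (k % 3), 5.0 * (k // 3), "target")
                  for k in range(9)]
    centers = {it.location_id: (it.x, it.y) for it in layout}
    fixations = []
    t = 0.0
    for i, loc in enumerate(locations):
        x, y = positions[i] if positions is not None else centers.get(loc, (99.0, 99.0))
        fixations.append(FixationEvent(t, t + 200.0, x, y, loc))
        t += 230.0
    return Trial(trial_id=trial_id, task="foraging", fixations=fixations,
                 saccades=[], layout=layout, timing={"array_onset": 0.0},
                 rewarded_fixation_ids=set(rewarded), completed=True)


def make_session(trials, session_id="s0", day=0, subject="m1", spikes=None):
    return Session(session_id=session_id, day=day, subject_id=subject,
                   trials=trials, spikes=spikes)


def make_spikes(counts_baseline, counts_stimulus, areas=None, n_trials=None):
    """SpikeData whose per-window counts are exactly the given arrays.

    ``counts_baseline`` / ``counts_stimulus``: (n_trials, n_units) ints;
    spikes are placed deterministically inside each window.
    """
    cb = np.asarray(counts_baseline)
    cs = np.asarray(counts_stimulus)
    n_tr, n_units = cb.shape
    areas = areas or ["V4"] * n_units
    units = [(f"u{i}", areas[i]) for i in range(n_units)]
    spike_times = {}
    for j, (uid, _) in enumerate(units):
        trains = []
        for i in range(n_tr):
            t_b = np.linspace(1.0, 199.0, int(cb[i, j])) if cb[i, j] else np.empty(0)
            t_s = 200.0 + np.linspace(1.0, 199.0, int(cs[i, j])) if cs[i, j] else np.empty(0)
            trains.append(np.concatenate([t_b, t_s]))
        spike_times[uid] = trains
    return SpikeData(units=units, spike_times=spike_times,
                     windows={"baseline_fixation": (0.0, 200.0),
                              "stimulus": (200.0, 400.0)})


@pytest.fixture
def foraging_session():
    """20 completed foraging trials cycling 0 -> 1 -> 2 -> 0 (deterministic)."""
    trials = [make_foraging_trial(i, [0, 1, 2, 0, 1, 2]) for i in range(20)]
    return make_session(trials)


@pytest.fixture
def gap_session():
    """10 completed gap trials, 3 with an in-gap window-leaving saccade."""
    trials = []
    for i in range(10):
        sacc = []
        if i < 3:
            sacc.append(SaccadeEvent(600.0, 4.0, 0.0))  # inside gap, 4 deg out
        sacc.append(SaccadeEvent(850.0, 8.0, 0.0))      # target saccade
        trials.append(make_gap_trial(i, sacc))
    return make_session(trials)
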