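"""End-to-end study runner: inclusion filters -> per-session metrics ->
metric series -> trend tests, with a reproducibility manifest.

The pipeline consumes a flat list of sessions (one task each, optionally
with spikes), applies the configured inclusion filters, computes every
applicable metric per session, assembles per-metric day courses and runs
the longitudinal slope tests.  Every exclusion decision is recorded as a
structured (JSON-serializable) log entry, since inclusion materially
shapes longitudinal results.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .behavior_metrics import (
    MIN_ENTROPY_TRIALS,
    entropy_zscore,
    foraging_metrics,
    preferential_metrics,
    superfluous_saccade_rate,
)
from .core_data import Session
from .errors import (
    MatchingFailedError,
    ParameterError,
    PopdisorgError,
    SessionExcludedError,
    UndefinedMetricError,
)
from .longitudinal_stats import (
    MetricSeries,
    SegmentedTrendResult,
    segmented_slope_comparison,
    slope_f_test,
)
from .population_metrics import (
    InclusionThresholds,
    average_autocorrelogram,
    fit_intrinsic_timescale,
    inclusion_report,
    noise_correlations,
    rate_matched_subsample,
    responsiveness_filter,
    unit_autocorrelogram,
)


@dataclass
class RunConfig:
    """Thresholds, analysis options and seeds for a full pipeline run.

    Threshold defaults are the study's: 20-30 sp/s rate band, R^2 > 0.5
    timescale inclusion, >= 35 trials for neural analyses, >= 20 completed
    trials for the entropy analysis, and 45 V4 / 10 7a / 100 cross-pair
    unit minima.
    """

    thresholds: InclusionThresholds = field(default_factory=InclusionThresholds)
    min_entropy_trials: int = MIN_ENTROPY_TRIALS
    n_entropy_shuffles: int = 1000
    entropy_convention: str = "row-sum"
    ridge_lambda: float = 1.0
    pca_var: float = 0.90
    timescale_method: str = "units"  # "units": mean tau over well-fit units;
    #                                   "population": fit the unit-averaged AC
    ac_bin_width_ms: float = 1.0
    rate_match_min_units: int = 2
    seed: int = 0
    treatment_onset_day: Optional[float] = None

    def __post_init__(self) -> None:
        if self.timescale_method not in ("units", "population"):
            raise ParameterError("timescale_method must be 'units' or 'population'")
        if self.n_entropy_shuffles < 2:
            raise ParameterError("n_entropy_shuffles must be >= 2")


@dataclass
class PipelineResult:
    metrics: pd.DataFrame          # session_id, subject_id, day, task, metric, value
    trends: pd.DataFrame           # metric, slope, intercept, f, p, n
    series: dict[str, MetricSeries]
    segmented: dict[str, SegmentedTrendResult]
    exclusions: list[dict]
    manifest: dict


def _behavior_metrics_for(session: Session, cfg: RunConfig,
                          log: list[dict]) -> dict[str, float]:
    out: dict[str, float] = {}
    task = session.task
    try:
        if task == "gap":
            out["superfluous_rate"] = superfluous_saccade_rate(session)
        elif task == "foraging":
            fm = foraging_metrics(session)
            out["reward_per_fixation"] = fm.reward_per_fixation
            out["mean_interfix_distance_deg"] = fm.mean_interfix_distance_deg
            out["revisit_rate"] = fm.revisit_rate
            try:
                er = entropy_zscore(session, n_shuffles=cfg.n_entropy_shuffles,
                                    seed=cfg.seed, convention=cfg.entropy_convention,
                                    min_completed=cfg.min_entropy_trials)
                out["entropy_bits"] = er.H
                if er.defined:
                    out["entropy_z"] = er.z
            except SessionExcludedError as e:
                log.append({"session_id": session.session_id, "analysis": "entropy",
                            "reason": str(e)})
        elif task == "preferential":
            pm = preferential_metrics(session)
            out["novelty_preference"] = pm.novelty_preference
            out["switches_per_trial"] = pm.switches_per_trial
            for cls, v in pm.fixation_duration_ms.items():
                out[f"fixation_duration_{cls}_ms"] = v
    except (UndefinedMetricError, PopdisorgError) as e:
        log.append({"session_id": session.session_id, "analysis": f"behavior/{task}",
                    "reason": str(e)})
    return out


def _neural_metrics_for(session: Session, cfg: RunConfig,
                        log: list[dict]) -> dict[str, float]:
    out: dict[str, float] = {}
    sp = session.spikes
    if sp is None:
        return out
    th = cfg.thresholds
    rep = inclusion_report(session.session_id, sp, len(session.completed_trials()), th)
    active = set(responsiveness_filter(sp, ratio=th.responsiveness_ratio))
    counts = sp.counts_in_window("baseline_fixation")

    if rep.passed["rsc"]:
        try:
            matched = rate_matched_subsample(
                counts, target=th.rate_band_hz, min_units=cfg.rate_match_min_units,
                seed=cfg.seed,
                unit_ids=[u for u in counts.unit_ids if u in active])
            for pair, key in (("V4-V4", "rsc_v4"), ("7a-7a", "rsc_7a"),
                              ("V4-7a", "rsc_v4_7a")):
                min_pairs = th.min_cross_pairs if pair == "V4-7a" else 1
                try:
                    res = noise_correlations(counts, pair, matched, min_pairs=min_pairs)
                    out[key] = res.mean_rsc
                except (UndefinedMetricError, SessionExcludedError) as e:
                    log.append({"session_id": session.session_id,
                                "analysis": f"rsc/{pair}", "reason": str(e)})
        except MatchingFailedError as e:
            log.append({"session_id": session.session_id, "analysis": "rate_matching",
                        "reason": str(e)})
    else:
        log.append({"session_id": session.session_id, "analysis": "rsc",
                    "reason": "inclusion filter failed",
                    "report": {k: v for k, v in asdict(rep).items() if k != "passed"}})

    if rep.passed["timescale"]:
        v4_units = [u for u in sp.unit_ids if sp.areas[u] == "V4" and u in active]
        acs = []
        for u in v4_units:
            try:
                acs.append(unit_autocorrelogram(sp, u, bin_width=cfg.ac_bin_width_ms))
            except UndefinedMetricError:
                continue
        if acs:
            if cfg.timescale_method == "population":
                fit = fit_intrinsic_timescale(average_autocorrelogram(acs),
                                              r2_threshold=th.r2_threshold)
                if fit.included:
                    out["tau_ms"] = fit.tau_ms
                else:
                    log.append({"session_id": session.session_id,
                                "analysis": "timescale",
                                "reason": f"pooled fit R^2 {fit.r_squared:.3f} <= "
                                          f"{th.r2_threshold}"})
            else:
                taus = [f.tau_ms for f in
                        (fit_intrinsic_timescale(ac, r2_threshold=th.r2_threshold)
                         for ac in acs) if f.included]
                if taus:
                    out["tau_ms"] = float(np.mean(taus))
                else:
                    log.append({"session_id": session.session_id,
                                "analysis": "timescale",
                                "reason": "no unit passed the R^2 criterion"})
    return out


def run_pipeline(sessions: Sequence[Session], config: RunConfig = RunConfig()) -> PipelineResult:
    """Compute all applicable metrics per session and trend tests per metric.

    Sessions sharing a day contribute the mean of their values for that day
    to the metric's series.  Raises :class:`SessionExcludedError` if no
    session yields any metric.
    """
    if not sessions:
        raise ParameterError("no sessions given")
    log: list[dict] = []
    rows = []
    for sess in sessions:
        vals = {}
        vals.update(_behavior_metrics_for(sess, config, log))
        vals.update(_neural_metrics_for(sess, config, log))
        for metric, value in vals.items():
            rows.append({"session_id": sess.session_id, "subject_id": sess.subject_id,
                         "day": sess.day, "task": sess.task, "metric": metric,
                         "value": value})
    metrics = pd.DataFrame(rows, columns=["session_id", "subject_id", "day",
                                          "task", "metric", "value"])
    if metrics.empty:
        raise SessionExcludedError("no session produced any metric")

    onset = config.treatment_onset_day
    if onset is None:
        treated_days = [s.day for s in sessions if s.treatment_flag]
        onset = float(min(treated_days)) if treated_days else None

    subject = sessions[0].subject_id
    series: dict[str, MetricSeries] = {}
    trend_rows = []
    segmented: dict[str, SegmentedTrendResult] = {}
    for metric, sub in metrics.groupby("metric"):
        per_day = sub.dropna(subset=["value"]).groupby("day")["value"].mean()
        if per_day.size < 3:
            log.append({"analysis": f"trend/{metric}",
                        "reason": f"only {per_day.size} days with values"})
            continue
        ms = MetricSeries(subject_id=subject, metric=metric,
                          days=per_day.index.to_numpy(dtype=float),
                          values=per_day.to_numpy(),
                          treatment_onset_day=onset)
        series[metric] = ms
        tr = slope_f_test(ms)
        trend_rows.append({"metric": metric, "slope": tr.slope,
                           "intercept": tr.intercept, "f": tr.f_statistic,
                           "p": tr.p_value, "n_days": tr.n_points})
        if onset is not None:
            try:
                segmented[metric] = segmented_slope_comparison(ms, onset)
            except ParameterError as e:
                log.append({"analysis": f"segmented/{metric}", "reason": str(e)})
    trends = pd.DataFrame(trend_rows, columns=["metric", "slope", "intercept",
                                               "f", "p", "n_days"])
    manifest = {
        "popdisorg_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "config": _config_dict(config),
        "n_sessions": len(sessions),
        "treatment_onset_day": onset,
        "n_exclusions": len(log),
    }
    return PipelineResult(metrics=metrics, trends=trends, series=series,
                          segmented=segmented, exclusions=log, manifest=manifest)


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["thresholds"]["rate_band_hz"] = list(config.thresholds.rate_band_hz)
    return d


def write_results(result: PipelineResult, outdir: str) -> None:
    """Write tidy CSV tables, the exclusion log (JSON lines) and the manifest."""
    import os

    os.makedirs(outdir, exist_ok=True)
    result.metrics.to_csv(os.path.join(outdir, "metrics.csv"), index=False)
    result.trends.to_csv(os.path.join(outdir, "trends.csv"), index=False)
    with open(os.path.join(outdir, "exclusions.jsonl"), "w") as fh:
        for entry in result.exclusions:
            fh.write(json.dumps(entry) + "\n")
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=1)
        fh.write("\n")
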