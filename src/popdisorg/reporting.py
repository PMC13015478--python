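"""Human-readable summaries and per-metric day-course plots."""

from __future__ import annotations

import os
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import ParameterError
from .pipeline import PipelineResult


def report(result: PipelineResult, outdir: str) -> list[str]:
    """Write one day-course figure per metric plus a text summary.

    Each figure shows the per-day values, the fitted trend line and its
    p-value; if a treatment onset is known the epoch is marked.  Metrics
    with no series (excluded everywhere) are omitted with a logged notice.
    Returns the list of files written.
    """
    if result.metrics.empty:
        raise ParameterError("empty results; nothing to report")
    os.makedirs(outdir, exist_ok=True)
    written = []
    onset: Optional[float] = result.manifest.get("treatment_onset_day")
    lines = ["metric            slope/day      F        p      n_days",
             "-" * 58]
    for _, row in result.trends.iterrows():
        metric = row["metric"]
        ms = result.series[metric]
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(ms.days, ms.values, "o", ms=3, color="0.3")
        xs = ms.days
        ax.plot(xs, row["intercept"] + row["slope"] * xs, "-", color="crimson",
                label=f"slope={row['slope']:.2e}, p={row['p']:.3g}")
        if onset is not None and xs.min() <= onset <= xs.max():
            ax.axvline(onset, color="steelblue", ls="--", lw=1, label="treatment onset")
        ax.set_xlabel("day since disease onset")
        ax.set_ylabel(metric)
        ax.legend(fontsize=7, frameon=False)
        fig.tight_layout()
        path = os.path.join(outdir, f"{metric}.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
        lines.append(f"{metric:<18s} {row['slope']:+.3e} {row['f']:8.2f} "
                     f"{row['p']:8.3g} {int(row['n_days']):6d}")
        if metric in result.segmented:
            seg = result.segmented[metric]
            lines.append(f"  pre/post slopes: {seg.slope_pre:+.3e} / "
                         f"{seg.slope_post:+.3e} (slope-equality p={seg.p_value:.3g})")
    missing = set(result.metrics["metric"].unique()) - set(result.trends["metric"])
    for m in sorted(missing):
        lines.append(f"{m:<18s} (no trend: too few days with values)")
    summary = os.path.join(outdir, "summary.txt")
    with open(summary, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    written.append(summary)
    return written
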