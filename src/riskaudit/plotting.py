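"""Optional matplotlib rendering of the audit's figures.

All figure *data* is exportable as delimited text without a graphics
backend; these helpers only draw.  matplotlib is imported lazily so the
core package works without it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_validation_curve(curve, path) -> Path:
    """Validation plot: per-bin observed vs predicted with Wilson bars,
    LOWESS overlay, diagonal, threshold marker, and per-class score
    histograms (log counts) underneath."""
    plt = _plt()
    fig, (ax, axh) = plt.subplots(
        2, 1, figsize=(6, 6), sharex=True, height_ratios=[3, 1]
    )
    xs = [b.mean_predicted for b in curve.bins]
    ys = [b.observed_proportion for b in curve.bins]
    lo = [b.observed_proportion - b.wilson_lo for b in curve.bins]
    hi = [b.wilson_hi - b.observed_proportion for b in curve.bins]
    ax.errorbar(xs, ys, yerr=[lo, hi], fmt="o", color="k", capsize=3, label="risk groups")
    ax.plot(curve.lowess_x, curve.lowess_y, "-", color="tab:blue", label="LOWESS")
    ax.plot([0, 1], [0, 1], "--", color="gray", label="ideal")
    ax.axvline(curve.threshold, color="red", lw=1)
    ax.set_ylabel("observed event proportion")
    ax.legend(loc="upper left", fontsize=8)
    centers = 0.5 * (curve.hist_edges[:-1] + curve.hist_edges[1:])
    width = np.diff(curve.hist_edges)
    axh.bar(centers, curve.hist_nonevent, width=width, alpha=0.6, label="non-event")
    axh.bar(centers, curve.hist_event, width=width, alpha=0.6, label="event")
    axh.set_yscale("symlog")
    axh.set_xlabel("predicted risk")
    axh.set_ylabel("count")
    axh.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_group_intervals(panels, metric: str, path, title: str = "") -> Path:
    """Forest-style plot of one metric's group estimates with intervals,
    event rates in parentheses after the group labels."""
    plt = _plt()
    rows = [p for p in panels if p.assessable and metric in p.estimates]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(rows) + 1.5))
    for i, p in enumerate(rows):
        e = p.estimates[metric]
        ax.plot([e.ci_lo, e.ci_hi], [i, i], "-", color="gray")
        ax.plot(e.point, i, "ko")
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels(
        [f"{p.attribute}:{p.level} ({p.event_rate_pct:.1f}%)" for p in rows], fontsize=8
    )
    ax.set_xlabel(metric)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_citl(estimates, path, title: str = "") -> Path:
    """Calibration-in-the-large intervals per group around the zero line."""
    plt = _plt()
    rows = [e for e in estimates if e.assessable]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(rows) + 1.5))
    for i, e in enumerate(rows):
        ax.plot([e.ci_lo, e.ci_hi], [i, i], "-", color="gray")
        ax.plot(e.rel_diff, i, "ko")
    ax.axvline(0.0, color="red", ls="--", lw=1)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([f"{e.attribute}:{e.level}" for e in rows], fontsize=8)
    ax.set_xlabel("(mean predicted − observed) / observed")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_comorbidity_curves(curves, attribute: str, path, title: str = "") -> Path:
    """Mean Charlson score vs pooled risk percentile, one line per level."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        if c.attribute != attribute:
            continue
        ax.plot(c.percentiles, c.mean_charlson, label=c.level)
    ax.set_xlabel("risk score percentile (pooled)")
    ax.set_ylabel("mean Charlson score")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
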