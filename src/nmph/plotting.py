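"""Figure helpers: representational-change summaries and aligned MDS panels."""

from __future__ import annotations

import numpy as np

from .analysis import aggregate_runs, correlation_series, mds_embed_align


def plot_correlation_timecourse(result, ax=None, color="purple"):
    """Per-run within-pair correlation over test epochs (one line per run)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    series = correlation_series(result)
    epochs = np.arange(series.shape[0])
    for run in range(series.shape[1]):
        ax.plot(epochs, series[:, run], color=color, alpha=0.25, lw=1)
    mean, lo, hi = aggregate_runs(series)
    ax.plot(epochs, mean, color="black", lw=2, label="mean")
    ax.fill_between(epochs, lo, hi, color="gray", alpha=0.3)
    ax.axhline(np.nanmean(series[0]), color="gray", ls="--", lw=1)
    ax.set_xlabel("test epoch")
    ax.set_ylabel("within-pair correlation")
    ax.set_ylim(-1.05, 1.05)
    return ax


def plot_mds(result, ax=None, jitter=0.0, seed=0, max_runs=None):
    """Aligned MDS of (pairmate1/2 x before/after) hidden patterns per run.

    ``jitter`` adds plotting-only Gaussian displacement so coincident points
    remain visible.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rng = np.random.default_rng(seed)
    n = result.n_runs if max_runs is None else min(max_runs, result.n_runs)
    styles = {
        0: dict(marker="o", color="tab:blue", label="pairmate1 before"),
        1: dict(marker="o", color="tab:red", label="pairmate2 before"),
        2: dict(marker="^", color="tab:blue", label="pairmate1 after"),
        3: dict(marker="^", color="tab:red", label="pairmate2 after"),
    }
    pts = {i: [] for i in styles}
    for run in range(n):
        p1 = int(result.pairmate1[run])
        p2 = 1 - p1
        coords = mds_embed_align(
            result.hidden[0, p1, run], result.hidden[0, p2, run],
            result.hidden[-1, p1, run], result.hidden[-1, p2, run])
        if not np.all(np.isfinite(coords)):
            continue
        coords = coords + jitter * rng.standard_normal(coords.shape)
        for i in styles:
            pts[i].append(coords[i])
    for i, style in styles.items():
        if pts[i]:
            xy = np.array(pts[i])
            ax.scatter(xy[:, 0], xy[:, 1], s=18, alpha=0.6, **style)
    ax.legend(fontsize=7)
    ax.set_xlabel("MDS dim 1")
    ax.set_ylabel("MDS dim 2")
    ax.set_aspect("equal")
    return ax
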