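"""Bar-chart summaries of re-cache proportions.

Mirrors the usual presentation of cache-protection experiments: mean
proportion of caches re-cached per condition (and per tray where the
design contrasts trays), with standard errors across birds.
"""

from __future__ import annotations

from .experiments import RunResult, summarize_run


def plot_recache_bars(run: RunResult, title: str = "", ax=None):
    """Bar chart of a single run's re-cache proportions.

    Returns the matplotlib Axes.  Imports matplotlib lazily so headless
    batch runs never touch a display backend unless asked to plot.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    summary = summarize_run(run)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    labels = [f"{c}\n{t}" if t != "all" else str(c)
              for c, t in zip(summary.condition, summary.tray)]
    ax.bar(range(len(summary)), summary["mean"], yerr=summary["se"],
           capsize=3, color="0.6", edgecolor="black")
    ax.set_xticks(range(len(summary)), labels, fontsize=8)
    ax.set_ylabel("proportion of caches re-cached")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    return ax
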