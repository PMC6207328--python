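"""Convenience figures following the package's reporting conventions:
zero-anchored fixed-width histograms and mean/quartile violin summaries.
These are for quick inspection; they carry no analysis logic.
"""

from __future__ import annotations

import numpy as np

from .stats import HistogramSpec, histogram, summarize

__all__ = ["plot_histogram", "plot_violins"]


def plot_histogram(values, spec: HistogramSpec, ax=None, label: str = "",
                   **bar_kwargs):
    """Bar plot of a fixed-width histogram; annotates mean ± SD, n."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    edges, counts = histogram(values, spec)
    ax.bar(edges[:-1], counts, width=spec.bin_width, align="edge",
           edgecolor="black", **bar_kwargs)
    ax.set_ylabel("count")
    s = summarize(values)
    ax.set_title(f"{label + ': ' if label else ''}{s}")
    return ax


def plot_violins(groups, labels, ax=None, ylabel: str = ""):
    """Violin plot with quartile lines and a dotted mean line per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = [np.asarray(g, dtype=float) for g in groups]
    parts = ax.violinplot(data, showextrema=False)
    for i, vals in enumerate(data, start=1):
        s = summarize(vals)
        ax.hlines([s.q1, s.median, s.q3], i - 0.18, i + 0.18,
                  color="black", lw=0.8)
        ax.hlines(s.mean, i - 0.25, i + 0.25, color="black",
                  lw=1.2, linestyle=":")
    ax.set_xticks(range(1, len(data) + 1), labels)
    if ylabel:
        ax.set_ylabel(ylabel)
    return ax
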