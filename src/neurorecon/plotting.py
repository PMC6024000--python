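"""Optional matplotlib figures for pipeline reports.

Imported lazily by the CLI; the library itself never requires matplotlib
at import time.
"""

from __future__ import annotations

import numpy as np


def plot_layer_accuracy(table, ax=None):
    """Bar chart of per-layer mean prediction accuracy (Pearson r)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.bar(table["layer"], table["mean_r"], color="steelblue")
    ax.set_ylabel("mean prediction accuracy (r)")
    ax.tick_params(axis="x", rotation=60)
    ax.set_ylim(bottom=0)
    return ax


def plot_area_contributions(report: dict, layer_order, ax=None):
    """Stacked per-layer visual-area proportions of the significant voxels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    areas = sorted({a for props in report.values() for a in props})
    bottom = np.zeros(len(layer_order))
    for a in areas:
        vals = np.array([report[l].get(a, 0.0) for l in layer_order])
        ax.bar(layer_order, vals, bottom=bottom, label=a)
        bottom += vals
    ax.set_ylabel("proportion of significant voxels")
    ax.tick_params(axis="x", rotation=60)
    ax.legend(ncol=4, fontsize=8)
    return ax
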