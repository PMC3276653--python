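"""Basic plots: scan curves and subtype dendrograms (matplotlib optional)."""

from __future__ import annotations

import numpy as np


def plot_scan(scans, ax=None, show_threshold=True):
    """LRT curves for one scan or a {name: QTLScanResult} dict."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    if not isinstance(scans, dict):
        scans = {"scan": scans}
    for name, scan in scans.items():
        (line,) = ax.plot(scan.positions, scan.lrt, label=name)
        if show_threshold and scan.threshold is not None:
            ax.axhline(scan.threshold.value, color=line.get_color(), ls="--", lw=0.8)
    ax.set_xlabel("position (cM)")
    ax.set_ylabel("LRT")
    ax.legend(fontsize=8)
    return ax


def plot_dendrogram(assignment, trait=None, ax=None):
    """Dendrogram of the animal clustering, leaves labelled by animal id."""
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    labels = list(assignment.labels.index)
    hierarchy.dendrogram(assignment.linkage, labels=labels, ax=ax, leaf_font_size=7)
    ax.set_ylabel("merge height")
    return ax
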