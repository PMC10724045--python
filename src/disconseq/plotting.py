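"""Positional-variance and event-centre figures for fitted sequences."""

from __future__ import annotations

import numpy as np


def positional_variance_diagram(result, path=None, ax=None, cmap: str = "Blues"):
    """Heatmap of how often each region occupies each sequence position.

    Rows are ordered by the final maximum-likelihood sequence (earliest event
    at the top); darker cells mean the region's position is more certain
    across bootstraps.
    """
    import matplotlib.pyplot as plt

    if result.positional_variance is None:
        raise ValueError("result carries no bootstrap positional variance")
    pv = result.positional_variance[result.sequence]
    labels = result.sequence_ids
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(labels) + 1.5))
    im = ax.imshow(pv, cmap=cmap, vmin=0, vmax=1, aspect="auto")
    ax.set_yticks(range(len(labels)), labels=labels, fontsize=7)
    ax.set_xticks(range(pv.shape[1]), labels=[str(j + 1) for j in range(pv.shape[1])], fontsize=7)
    ax.set_xlabel("sequence position")
    ax.set_title("Positional variance across bootstraps")
    ax.figure.colorbar(im, ax=ax, label="fraction of bootstraps")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def event_centre_plot(result, path=None, ax=None):
    """Event centres (mean bootstrap position, 1-based) with standard errors,
    ordered by the final sequence."""
    import matplotlib.pyplot as plt

    if result.event_centres is None:
        raise ValueError("result carries no event centres")
    order = result.sequence
    labels = result.sequence_ids
    centres = result.event_centres[order]
    se = result.event_centre_se[order]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(labels) + 1.5))
    y = np.arange(len(labels))
    ax.errorbar(centres, y, xerr=se, fmt="o", color="tab:blue", ecolor="gray", capsize=2)
    ax.set_yticks(y, labels=labels, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("event centre (mean bootstrap position ± SE)")
    ax.set_title("Event-centre variance")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
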