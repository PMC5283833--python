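"""Figure rendering for curves, preference landscapes and context histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_curve(curves, path=None, ax=None, labels=None, title=None):
    """Plot one or more paired-choice probability curves with CI bands.

    ``curves`` is a DataFrame (bin, n, k, p, lo, hi) or a list of them.
    """
    if not isinstance(curves, (list, tuple)):
        curves = [curves]
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    for i, c in enumerate(curves):
        if len(c) == 0:
            continue
        lbl = labels[i] if labels else None
        ax.plot(c["dn"], c["p"], "o-", label=lbl)
        ax.fill_between(c["dn"], c["lo"], c["hi"], alpha=0.25)
    ax.axhline(0.5, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("recently-used difference (location 1 - location 2)")
    ax.set_ylabel("P(location 1 chosen)")
    ax.set_ylim(0, 1)
    if labels:
        ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax


def plot_preference_landscape(panels: dict, path=None):
    """Render per-feature and combined preference panels on one figure."""
    names = [k for k in panels if not k.startswith("_")]
    ncol = 4
    nrow = int(np.ceil(len(names) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.6 * nrow))
    for ax, name in zip(np.ravel(axes), names):
        v = panels[name]
        vmax, vmin = v.max(), v.min()
        vn = (v - vmin) / (vmax - vmin) if vmax > vmin else np.zeros_like(v)
        ax.imshow(vn, origin="lower", cmap="viridis")
        ax.set_title(name, fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    for ax in np.ravel(axes)[len(names):]:
        ax.axis("off")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_hist_diff(result: dict, metric_pair, path=None):
    """Render a signed context-difference histogram (red over-, blue
    under-represented)."""
    diff = result["diff"]
    lim = np.abs(diff).max() or 1.0
    fig, ax = plt.subplots(figsize=(4, 3.6))
    ex, ey = result["edges"]
    im = ax.imshow(
        diff.T,
        origin="lower",
        aspect="auto",
        cmap="RdBu_r",
        vmin=-lim,
        vmax=lim,
        extent=(ex[0], ex[-1], ey[0], ey[-1]),
    )
    ax.set_xlabel(metric_pair[0])
    ax.set_ylabel(metric_pair[1])
    fig.colorbar(im, ax=ax, label="context - overall")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
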