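"""Optional boxplot-panel rendering of cluster diagnostics (cosmetic).

Requires matplotlib (the ``plot`` extra).
"""

from __future__ import annotations


def plot_diagnostics(diagnostics, quantity: str = "intra_sigma", ax=None,
                     show_states: bool = True):
    """Notched boxplots of a per-cluster quantity, one box per cluster.

    ``quantity`` is one of ``intra_sigma``, ``intra_rmsd`` or ``rg``.
    Boxes are drawn from the precomputed summaries (quartiles, notches,
    whiskers, outliers), mirroring the panel layout used for the model
    clustering figures.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(diagnostics), 3))
    state_colors = {"meta-stable": "tab:blue", "transition": "tab:red",
                    "intermediate": "0.7"}
    for d in diagnostics:
        b = getattr(d, quantity)
        x = d.cluster_id
        if b is None:
            ax.plot(x, 0, marker="x", color="0.5")
            continue
        color = state_colors[d.state] if show_states else "0.7"
        ax.add_patch(plt.Rectangle((x - 0.3, b.q1), 0.6, b.q3 - b.q1,
                                   facecolor=color, alpha=0.6,
                                   edgecolor="black"))
        ax.hlines(b.median, x - 0.3, x + 0.3, color="black")
        ax.vlines(x, b.whisker_low, b.q1, color="black", lw=0.8)
        ax.vlines(x, b.q3, b.whisker_high, color="black", lw=0.8)
        ax.hlines([b.notch_low, b.notch_high], x - 0.15, x + 0.15,
                  color="black", lw=0.6, linestyles=":")
        if b.outliers.size:
            ax.plot([x] * b.outliers.size, b.outliers, "o", mfc="none",
                    mec="black", ms=3)
    ax.set_xlabel("cluster (temporal order)")
    ax.set_ylabel(quantity.replace("_", " "))
    ax.set_xticks([d.cluster_id for d in diagnostics])
    return ax
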