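"""Minimal plots: stacked outcome proportions across k, and trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .dynamics import OUTCOMES, Trajectory

__all__ = ["plot_sweep", "plot_trajectory"]

_COLORS = {"only_i": "0.5", "only_j": "darkgreen", "both": "limegreen", "neither": "firebrick"}


def plot_sweep(table, path=None, ax=None):
    """Stacked outcome proportions against the persistence probability k.

    One panel per pairing when the table covers several pairings.
    """
    pairings = table["pairing"].unique()
    fig, axes = plt.subplots(
        1, len(pairings), figsize=(4 * len(pairings), 3.2), sharey=True, squeeze=False
    )
    for ax_, pairing in zip(axes.ravel(), pairings):
        sub = table[table["pairing"] == pairing].sort_values("k")
        bottom = None
        for outcome in OUTCOMES:
            ax_.bar(sub["k"], sub[outcome], width=0.08, bottom=bottom,
                    label=outcome, color=_COLORS[outcome])
            bottom = sub[outcome].to_numpy() if bottom is None else bottom + sub[outcome].to_numpy()
        ax_.set_xlabel("autocorrelation k")
        ax_.set_title(pairing, fontsize=9)
    axes[0, 0].set_ylabel("proportion of replicates")
    axes[0, -1].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_trajectory(traj: Trajectory, path=None):
    """Both abundance series with the good/bad sequence annotated on top."""
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.plot(traj.times, traj.n_i, color="0.4", label=f"i ({traj.meta.get('strategy_i', '')})")
    ax.plot(traj.times, traj.n_j, color="darkgreen", label=f"j ({traj.meta.get('strategy_j', '')})")
    ax.set_xlabel("generation")
    ax.set_ylabel("abundance")
    ax.set_title(traj.env.signs()[: min(len(traj), 100)], fontsize=6, family="monospace")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
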