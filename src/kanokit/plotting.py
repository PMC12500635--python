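"""Plot scaffolding for the better-worse plane and the screening arcs."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .scoring import ScreeningConfig

__all__ = ["better_worse_plot", "sensitivity_matrix_plot"]

_DIM_MARKERS = ["o", "s", "^", "D", "v", "P", "X"]


def _axes_base(figsize=(6.5, 6.0)):
    fig, ax = plt.subplots(figsize=figsize)
    ax.set_xlim(0, 1.0)
    ax.set_ylim(0, 1.0)
    ax.set_xlabel("Better / SI")
    ax.set_ylabel("|Worse| / |DSI|")
    ax.set_aspect("equal")
    return fig, ax


def better_worse_plot(results: pd.DataFrame, annotate: bool = True):
    """Scatter of (better, |worse|) with quadrant reference lines at 0.5.

    The 0.5 reference lines are a presentation convention only; no analysis
    depends on them.
    """
    fig, ax = _axes_base()
    ax.axvline(0.5, color="grey", lw=0.8, ls="--")
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    x = results["better"].to_numpy(float)
    y = np.abs(results["worse"].to_numpy(float))
    ax.scatter(x, y, s=22, c="tab:blue", zorder=3)
    if annotate:
        for item_id, xi, yi in zip(results.index, x, y):
            ax.annotate(str(item_id), (xi, yi), fontsize=6,
                        textcoords="offset points", xytext=(3, 3))
    ax.set_title("Better-worse coefficient diagram")
    fig.tight_layout()
    return fig


def sensitivity_matrix_plot(results: pd.DataFrame, config: ScreeningConfig | None = None):
    """Scatter of (better, |worse|) with the element / key-element arcs."""
    config = config or ScreeningConfig()
    fig, ax = _axes_base()
    ax.set_xlim(0, max(1.0, config.key_radius * 1.05))
    ax.set_ylim(0, max(1.0, config.key_radius * 1.05))
    theta = np.linspace(0, np.pi / 2, 200)
    for radius, name, colour in (
        (config.element_radius, f"element line (r={config.element_radius})", "tab:orange"),
        (config.key_radius, f"key element line (r={config.key_radius})", "tab:red"),
    ):
        ax.plot(radius * np.cos(theta), radius * np.sin(theta), color=colour,
                lw=1.2, label=name)
    x = results["better"].to_numpy(float)
    y = np.abs(results["worse"].to_numpy(float))
    ax.scatter(x, y, s=22, c="tab:blue", zorder=3)
    for item_id, xi, yi in zip(results.index, x, y):
        ax.annotate(str(item_id), (xi, yi), fontsize=6,
                    textcoords="offset points", xytext=(3, 3))
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("Sensitivity screening matrix")
    fig.tight_layout()
    return fig
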