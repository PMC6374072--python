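"""Minimal plotting helpers (optional; requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .condorcet import ErrorRegionMap


def plot_region_map(m: ErrorRegionMap, ax=None):
    """Shade the marked cells of an error-region map on (p, ratio) axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.pcolormesh(m.p_grid, m.ratio_grid, m.marked.T.astype(float),
                  cmap="Greys", vmin=0, vmax=1.5, shading="nearest")
    ax.set_yscale("log")
    ax.set_xlabel("prior probability of state +")
    ax.set_ylabel("cost ratio $C_{FP}/C_{FN}$")
    ax.set_title(f"error map: {m.which}")
    return ax


def plot_accuracy_curve(df, ax=None):
    """Plot exact (and simulated, if present) group accuracy against N."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if "accuracy" in df:
        ax.plot(df["n"], df["accuracy"], "-", label="exact")
    if "sim_accuracy" in df:
        ax.plot(df["n"], df["sim_accuracy"], ".", ms=3, alpha=0.6, label="simulated")
    ax.axhline(df["individual_accuracy"].iloc[0], ls="--", color="r",
               label="individual accuracy")
    ax.axhline(df["asymptotic_limit"].iloc[0], ls="-.", color="k",
               label="large-N limit")
    ax.set_xlabel("group size N")
    ax.set_ylabel("group accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
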