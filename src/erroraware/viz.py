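"""Minimal plotting helpers (topographies and time courses)."""

from __future__ import annotations

import numpy as np

from .montage import Montage


def plot_topography(values: np.ndarray, montage: Montage, ax=None,
                    title: str = "", mask: np.ndarray | None = None):
    """Scatter topography of per-channel values on the ring layout."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x, y = montage.positions.T
    vmax = np.nanmax(np.abs(values)) or 1.0
    sc = ax.scatter(x, y, c=values, s=120, cmap="RdBu_r",
                    vmin=-vmax, vmax=vmax, edgecolors="k", linewidths=0.4)
    if mask is not None and mask.any():
        ax.scatter(x[mask], y[mask], s=14, c="k")
    head = plt.Circle((0, 0), 1.05, fill=False, color="k")
    ax.add_patch(head)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    plt.colorbar(sc, ax=ax, shrink=0.7)
    return ax


def plot_timecourse(times: np.ndarray, values: np.ndarray, ax=None,
                    mask: np.ndarray | None = None, title: str = "",
                    ylabel: str = ""):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(times * 1000, values, color="C0")
    if mask is not None and mask.any():
        ax.fill_between(times * 1000, np.nanmin(values), np.nanmax(values),
                        where=mask, alpha=0.2, color="gray")
    ax.axvline(0, color="k", lw=0.5)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    return ax
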