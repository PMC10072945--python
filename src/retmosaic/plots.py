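"""Static diagnostic plots (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import nn_distances

__all__ = ["plot_ri_vs_density", "plot_nn_histogram", "plot_mosaic", "plot_ri_trajectory"]


def _save(fig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_ri_vs_density(densities, ris, path, fit=True):
    """Scatter of per-type final density against final RI."""
    d = np.asarray(densities, dtype=float)
    r = np.asarray(ris, dtype=float)
    ok = np.isfinite(r)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(d[ok], r[ok], "o", ms=5, alpha=0.8)
    if fit and ok.sum() >= 3:
        coef = np.polyfit(d[ok], r[ok], 1)
        xs = np.linspace(d[ok].min(), d[ok].max(), 50)
        ax.plot(xs, np.polyval(coef, xs), "r-", lw=1)
    ax.set_xlabel("final density (cells/mm²)")
    ax.set_ylabel("Regularity Index")
    return _save(fig, path)


def plot_nn_histogram(points, path, window=None, bins=30):
    """Histogram of nearest-neighbour distances of one mosaic."""
    d = nn_distances(points, window=window)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(d, bins=bins, color="steelblue", edgecolor="white")
    ax.set_xlabel("nearest-neighbour distance (µm)")
    ax.set_ylabel("cells")
    ax.set_title(f"RI = {d.mean() / d.std(ddof=1):.2f}" if d.std(ddof=1) > 0 else "lattice")
    return _save(fig, path)


def plot_mosaic(points_by_label, path, window=None):
    """Planar scatter of one or more labelled point populations."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, pts in points_by_label.items():
        pts = np.asarray(pts)
        ax.plot(pts[:, 0], pts[:, 1], "o", ms=3, alpha=0.7, label=str(label))
    if window is not None:
        xmin, xmax, ymin, ymax = window
        ax.add_patch(plt.Rectangle((xmin, ymin), xmax - xmin, ymax - ymin,
                                   fill=False, ls="--", color="grey"))
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_ri_trajectory(day_ri, path, label="average RI"):
    """RI against simulated day (one line per population or average)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    days = sorted(day_ri)
    ax.plot(days, [day_ri[d] for d in days], "-o", ms=4, label=label)
    ax.axhspan(1.8, 2.0, color="grey", alpha=0.25, label="random band")
    ax.set_xlabel("simulated day")
    ax.set_ylabel("Regularity Index")
    ax.legend(fontsize=8)
    return _save(fig, path)
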