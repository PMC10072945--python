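"""Spatial statistics of retinal mosaics.

The central quantity is the Regularity Index (RI): the mean of the per-cell
nearest-neighbour distances divided by their standard deviation.  Uniform
random point patterns score between 1.8 and 2; regular mosaics score higher;
a perfect lattice has zero nearest-neighbour spread and is reported as an
infinite-regularity condition (``inf``).

The exclusion factor quantifies how much two point populations avoid each
other: the fraction of cells whose nearest cell of the *other* population
lies strictly beyond a fixed exclusion diameter (32 µm by default, about
three SAC soma diameters), symmetrized over the two directions.  1 means
perfect exclusion, 0 total overlap.

All metrics operate on planar (x, y) coordinates in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "MosaicStats",
    "regularity_index",
    "nn_distances",
    "exclusion_factor",
    "closest_other_distances",
    "migration_distances",
    "death_rate",
    "pearson_r",
    "mann_whitney",
    "make_pattern",
    "mosaic_stats",
]


@dataclass
class MosaicStats:
    """Per-population summary of a mosaic."""

    population_label: str
    n_cells: int
    density: float  # cells mm^-2
    nn_distances: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    ri: float = np.nan
    exclusion_factor: float = np.nan
    mean_migration: float = np.nan
    migration_sd: float = np.nan
    death_rate: float = np.nan

    def to_dict(self) -> dict:
        return {
            "population_label": self.population_label,
            "n_cells": int(self.n_cells),
            "density_mm2": float(self.density),
            "ri": float(self.ri),
            "exclusion_factor": float(self.exclusion_factor),
            "mean_migration_um": float(self.mean_migration),
            "migration_sd_um": float(self.migration_sd),
            "death_rate": float(self.death_rate),
        }


def _as_xy(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("points must be an (n, 2+) array")
    return pts[:, :2]


def nn_distances(points, window: tuple[float, float, float, float] | None = None) -> np.ndarray:
    """Euclidean x,y distance from each point to its nearest other point.

    If ``window = (xmin, xmax, ymin, ymax)`` is given, neighbours are searched
    among *all* points but only points inside the window contribute a distance
    (border handling for simulation margins).
    """
    pts = _as_xy(points)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points for nearest-neighbour distances")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    d = d[:, 1]
    if window is not None:
        xmin, xmax, ymin, ymax = window
        keep = (
            (pts[:, 0] >= xmin)
            & (pts[:, 0] <= xmax)
            & (pts[:, 1] >= ymin)
            & (pts[:, 1] <= ymax)
        )
        d = d[keep]
    return d


def regularity_index(points, window=None, ddof: int = 1) -> float:
    """Mean / s.d. of the nearest-neighbour distance distribution.

    Uses the sample (n-1) standard deviation by default.  Returns ``inf``
    when all nearest-neighbour distances are identical (perfect lattice).
    Requires at least 3 contributing points.
    """
    pts = _as_xy(points)
    if pts.shape[0] < 3:
        raise ValueError("regularity index requires at least 3 points")
    d = nn_distances(pts, window=window)
    if d.shape[0] < 3:
        raise ValueError("fewer than 3 points inside the analysis window")
    sd = d.std(ddof=ddof)
    if sd == 0.0:
        return float("inf")
    return float(d.mean() / sd)


def closest_other_distances(pop_a, pop_b) -> np.ndarray:
    """For each A cell, the x,y distance to the nearest B cell."""
    a = _as_xy(pop_a)
    b = _as_xy(pop_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both populations must be non-empty")
    d, _ = cKDTree(b).query(a, k=1)
    return d


def exclusion_factor(pop_a, pop_b, diameter: float = 32.0, window=None) -> float:
    """Symmetrized fraction of cells beyond ``diameter`` µm of the other population.

    1 = perfect exclusion (every cell farther than the exclusion diameter from
    every cell of the other population), 0 = total overlap (coincident
    populations).  With ``window``, only cells inside it are scored (their
    nearest other-population cell may lie outside).
    """
    a = _as_xy(pop_a)
    b = _as_xy(pop_b)

    def frac(p, q):
        d = closest_other_distances(p, q)
        if window is not None:
            xmin, xmax, ymin, ymax = window
            keep = (
                (p[:, 0] >= xmin) & (p[:, 0] <= xmax)
                & (p[:, 1] >= ymin) & (p[:, 1] <= ymax)
            )
            d = d[keep]
        if d.shape[0] == 0:
            raise ValueError("no cells inside the analysis window")
        return float(np.mean(d > diameter))

    return 0.5 * (frac(a, b) + frac(b, a))


def migration_distances(positions, birth_positions, alive=None, survivors_only=True) -> np.ndarray:
    """Per-cell tangential (x,y) displacement |final - birth| in µm."""
    p = _as_xy(positions)
    b = _as_xy(birth_positions)
    d = np.hypot(p[:, 0] - b[:, 0], p[:, 1] - b[:, 1])
    if survivors_only and alive is not None:
        d = d[np.asarray(alive, dtype=bool)]
    return d


def death_rate(alive_counts) -> np.ndarray:
    """Per-day fraction of the initial population that has died.

    ``alive_counts`` is the census trajectory starting at step/day 0; the
    returned trajectory is non-decreasing and its last entry is the
    steady-state death rate.
    """
    counts = np.asarray(alive_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty trajectory")
    initial = counts[0]
    if initial <= 0:
        raise ValueError("initial census must be positive")
    return 1.0 - counts / initial


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (constant) input")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann–Whitney U statistic and two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def make_pattern(
    kind: str,
    density: float,
    extent: float,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.2,
    thin_to: float | None = None,
) -> np.ndarray:
    """Synthetic 2D point patterns with known regularity behaviour.

    Parameters
    ----------
    kind : "random" | "lattice" | "jittered_lattice" | "thinned".
    density : points per mm².
    extent : side of the square window, µm.
    jitter : for jittered lattices, s.d. of the Gaussian displacement as a
        fraction of the lattice pitch.
    thin_to : for "thinned", the surviving fraction of an initial random
        pattern at ``density`` (random thinning keeps the pattern Poisson).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kind = kind.lower()
    if density <= 0 or extent <= 0:
        raise ValueError("density and extent must be positive")
    n = max(1, int(round(density * 1e-6 * extent**2)))
    if kind == "random":
        return rng.uniform(0.0, extent, size=(n, 2))
    if kind in ("lattice", "jittered_lattice"):
        pitch = 1000.0 / np.sqrt(density)
        coords = np.arange(pitch / 2.0, extent, pitch)
        xx, yy = np.meshgrid(coords, coords)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        if kind == "jittered_lattice":
            pts = pts + rng.normal(0.0, jitter * pitch, size=pts.shape)
            pts = np.clip(pts, 0.0, extent)
        return pts
    if kind == "thinned":
        frac = 0.5 if thin_to is None else float(thin_to)
        pts = rng.uniform(0.0, extent, size=(n, 2))
        keep = rng.random(n) < frac
        return pts[keep]
    raise ValueError(f"unknown pattern kind {kind!r}")


def mosaic_stats(
    label: str,
    points,
    window=None,
    partner=None,
    exclusion_diameter: float = 32.0,
    birth_positions=None,
    alive=None,
    initial_count: int | None = None,
    area_mm2: float | None = None,
) -> MosaicStats:
    """Assemble the full per-population summary for one mosaic."""
    pts = _as_xy(points)
    if area_mm2 is None and window is not None:
        xmin, xmax, ymin, ymax = window
        area_mm2 = (xmax - xmin) * (ymax - ymin) * 1e-6
    d = nn_distances(pts, window=window) if pts.shape[0] >= 2 else np.empty(0)
    stats = MosaicStats(
        population_label=label,
        n_cells=pts.shape[0],
        density=pts.shape[0] / area_mm2 if area_mm2 else np.nan,
        nn_distances=d,
    )
    if d.size >= 3 and d.std(ddof=1) > 0:
        stats.ri = float(d.mean() / d.std(ddof=1))
    if partner is not None:
        stats.exclusion_factor = exclusion_factor(
            pts, partner, diameter=exclusion_diameter, window=window
        )
    if birth_positions is not None:
        m = migration_distances(points, birth_positions, alive=alive)
        if m.size:
            stats.mean_migration = float(m.mean())
            stats.migration_sd = float(m.std(ddof=1)) if m.size > 1 else 0.0
    if initial_count:
        stats.death_rate = 1.0 - pts.shape[0] / initial_count
    return stats
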