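"""Simulation space, cell agents, scheduler, and mechanical relaxation.

Cells are spheres of 7–14 µm diameter living in a thin slab (default
1000 × 1000 × 22 µm core plus a 150 µm analysis margin on each side, i.e. a
1300 µm bordered space).  160 simulation steps correspond to one day of
development and runs last at most 14 days (2240 steps).  Each step executes,
in order: substance secretion by living differentiated cells, diffusion,
behaviour updates (fate determination first until every cell is
differentiated, then death and migration), mechanical overlap relaxation,
diameter growth, and z-collapse toward the slab mid-plane.

The population is stored as a structure of arrays (:class:`CellPopulation`);
:class:`CellAgent` is a per-cell view used by the single-cell behaviour
wrappers and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._kernels import resolve_overlaps
from .grids import ConfigurationError, SubstanceGrid
from . import metrics as _metrics

__all__ = [
    "UNDIFFERENTIATED",
    "LAYER_NONE",
    "LAYER_GCL",
    "LAYER_INL",
    "CellAgent",
    "CellPopulation",
    "SimulationConfig",
    "TypeTable",
    "RunResult",
    "initialize_population",
    "relax_mechanics",
    "grow_cells",
    "collapse_z",
    "run",
]

UNDIFFERENTIATED = -1
LAYER_NONE, LAYER_GCL, LAYER_INL = 0, 1, 2
_LAYER_NAMES = {LAYER_NONE: "NONE", LAYER_GCL: "GCL", LAYER_INL: "INL"}


@dataclass
class CellAgent:
    """Single-cell view: one spherical cell."""

    id: int
    position: np.ndarray
    birth_position: np.ndarray
    diameter: float
    type_id: int = UNDIFFERENTIATED
    alive: bool = True
    layer: int = LAYER_NONE


@dataclass
class SimulationConfig:
    """Run configuration.

    Extents and densities follow the standard experiment layout: a square
    core (x, y) used for statistics, surrounded by a margin whose cells
    simulate but are excluded from analysis, and a z slab of 22 µm.
    ``initial_density`` defaults to 8600 cells/mm² when death is simulated
    (so ~3000 cells/mm² survive the ~65% loss) and should be 3000 otherwise.
    """

    core_extent: tuple[float, float, float] = (1000.0, 1000.0, 22.0)
    margin: float = 150.0
    steps_per_day: int = 160
    days: int = 14
    initial_density: float = 8600.0  # cells mm^-2
    mechanisms: frozenset[str] = frozenset({"CF", "CD", "CM"})
    condition: str = "FDM"
    seed: int = 1
    # substance field
    voxel_size: float = 2.0
    nu: float = 2.0
    mu: float = 0.0
    substeps: int | None = None
    boundary: str = "absorbing"
    grid_dtype: str = "float32"
    secretion_rate: float = 1.0
    # mechanics / geometry dynamics
    relax_iters: int = 3
    relax_tol: float = 0.005  # fraction of mean diameter
    diameter_range: tuple[float, float] = (7.0, 8.0)
    max_diameter: float = 14.0
    growth_start_day: float = 1.0
    growth_end_day: float = 6.0
    collapse_rate: float = 0.1  # µm per step toward the slab mid-plane
    # termination
    stop_on_steady: bool = True
    steady_death_frac: float = 0.001
    steady_move_frac: float = 0.001

    def __post_init__(self) -> None:
        self.mechanisms = frozenset(self.mechanisms)
        bad = self.mechanisms - {"CF", "CD", "CM"}
        if bad:
            raise ConfigurationError(f"unknown mechanisms {sorted(bad)}")
        if self.initial_density <= 0:
            raise ConfigurationError("initial_density must be positive")
        if self.steps_per_day <= 0 or self.days <= 0:
            raise ConfigurationError("steps_per_day and days must be positive")

    # ------------------------------------------------------------- geometry
    @property
    def extent(self) -> tuple[float, float, float]:
        """Full bordered extents (µm): core plus margins in x and y."""
        cx, cy, cz = self.core_extent
        return (cx + 2 * self.margin, cy + 2 * self.margin, cz)

    @property
    def window(self) -> tuple[float, float, float, float]:
        """Central analysis window (xmin, xmax, ymin, ymax) in µm."""
        cx, cy, _ = self.core_extent
        return (self.margin, self.margin + cx, self.margin, self.margin + cy)

    @property
    def window_area_mm2(self) -> float:
        cx, cy, _ = self.core_extent
        return cx * cy * 1e-6

    @property
    def area_mm2(self) -> float:
        ex, ey, _ = self.extent
        return ex * ey * 1e-6

    @property
    def max_steps(self) -> int:
        return self.steps_per_day * self.days

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        ex, ey, ez = self.extent
        v = self.voxel_size
        return (int(np.ceil(ex / v)), int(np.ceil(ey / v)), int(np.ceil(ez / v)))

    def scaled(self, core: float = 500.0, margin: float = 100.0,
               voxel_size: float = 4.0, **overrides) -> "SimulationConfig":
        """Desk-scale variant: smaller core/margin and a coarser voxel."""
        cz = self.core_extent[2]
        return replace(self, core_extent=(core, core, cz), margin=margin,
                       voxel_size=voxel_size, **overrides)


@dataclass
class TypeTable:
    """Cell types known to a run: names, target densities, substance wiring.

    ``densities`` are the per-type densities used for typed initialization
    (and as fate-choice weights); ``substance_of_type`` maps each type to the
    substance it secretes and senses — identity by default, shared for the
    one-cue SAC experiment.
    """

    names: list[str]
    densities: np.ndarray
    substance_of_type: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if len(self.names) != self.densities.size:
            raise ConfigurationError("names and densities length mismatch")
        if self.substance_of_type is None:
            self.substance_of_type = np.arange(self.n_types, dtype=np.int64)
        else:
            self.substance_of_type = np.asarray(self.substance_of_type, dtype=np.int64)

    @property
    def n_types(self) -> int:
        return len(self.names)

    @property
    def n_substances(self) -> int:
        return int(self.substance_of_type.max()) + 1


class CellPopulation:
    """Structure-of-arrays container for all cells of a run."""

    def __init__(self, pos, diameter, type_id=None, layer=None):
        pos = np.asarray(pos, dtype=np.float64)
        n = pos.shape[0]
        self.ids = np.arange(n, dtype=np.int64)
        self.pos = pos
        self.birth_pos = pos.copy()
        self.diameter = np.asarray(diameter, dtype=np.float64)
        self.initial_diameter = self.diameter.copy()
        self.type_id = (
            np.full(n, UNDIFFERENTIATED, dtype=np.int64)
            if type_id is None else np.asarray(type_id, dtype=np.int64)
        )
        self.alive = np.ones(n, dtype=bool)
        self.layer = (
            np.full(n, LAYER_NONE, dtype=np.int8)
            if layer is None else np.asarray(layer, dtype=np.int8)
        )

    def __len__(self) -> int:
        return self.pos.shape[0]

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def n_undifferentiated(self) -> int:
        return int((self.alive & (self.type_id == UNDIFFERENTIATED)).sum())

    def cell(self, i: int) -> CellAgent:
        return CellAgent(
            id=int(self.ids[i]),
            position=self.pos[i].copy(),
            birth_position=self.birth_pos[i].copy(),
            diameter=float(self.diameter[i]),
            type_id=int(self.type_id[i]),
            alive=bool(self.alive[i]),
            layer=int(self.layer[i]),
        )

    def to_dataframe(self, type_names: list[str] | None = None) -> pd.DataFrame:
        names = None
        if type_names is not None:
            lut = np.array(["UNDIFFERENTIATED"] + list(type_names), dtype=object)
            names = lut[self.type_id + 1]
        return pd.DataFrame(
            {
                "id": self.ids,
                "type_name": names if names is not None else self.type_id,
                "x_um": self.pos[:, 0],
                "y_um": self.pos[:, 1],
                "z_um": self.pos[:, 2],
                "diameter_um": self.diameter,
                "alive": self.alive,
                "layer": np.array([_LAYER_NAMES[int(v)] for v in self.layer], dtype=object),
            }
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def initialize_population(
    config: SimulationConfig, types: TypeTable, rng: np.random.Generator
) -> CellPopulation:
    """Place cells uniformly at random in the bordered slab.

    With CF enabled all cells start undifferentiated; otherwise types are
    pre-assigned so per-type counts match the table's densities (largest-
    remainder apportionment, then a random shuffle over cells).
    """
    ex, ey, ez = config.extent
    n = int(round(config.initial_density * config.area_mm2))
    if n < 1:
        raise ConfigurationError("configured density implies zero cells")
    pos = np.column_stack(
        [rng.uniform(0, ex, n), rng.uniform(0, ey, n), rng.uniform(0, ez, n)]
    )
    lo, hi = config.diameter_range
    diam = rng.uniform(lo, hi, n)
    type_id = None
    if "CF" not in config.mechanisms:
        type_id = _apportion_types(n, types.densities, rng)
    return CellPopulation(pos, diam, type_id=type_id)


def _apportion_types(n: int, densities: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w = densities / densities.sum()
    ideal = w * n
    counts = np.floor(ideal).astype(np.int64)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(ideal - counts))
        counts[order[:short]] += 1
    type_id = np.repeat(np.arange(densities.size, dtype=np.int64), counts)
    rng.shuffle(type_id)
    return type_id


def relax_mechanics(
    pop: CellPopulation,
    bounds: tuple[float, float, float],
    max_iter: int = 20,
    tol_frac: float = 0.005,
    moved_out: np.ndarray | None = None,
) -> float:
    """Iterative pairwise repulsion until the worst overlap is below tolerance.

    Overlapping pairs are displaced symmetrically along their centre axis by
    half the overlap each; positions are clamped to the slab.  Returns the
    final maximum overlap (µm).  ``moved_out`` (bool array over cells), when
    given, records which cells were displaced.
    """
    alive_idx = np.flatnonzero(pop.alive)
    if alive_idx.size < 2:
        return 0.0
    radii = pop.diameter[alive_idx] * 0.5
    tol = tol_frac * float(pop.diameter[alive_idx].mean())
    max_overlap = 0.0
    # candidate pairs found once per call with a small slack radius; the
    # per-iteration displacements are far smaller than the slack
    p = pop.pos[alive_idx]
    tree = cKDTree(p)
    pairs = tree.query_pairs(r=2.0 * radii.max() + 1.0, output_type="ndarray")
    if pairs.shape[0] == 0:
        return 0.0
    for _ in range(max_iter):
        p = pop.pos[alive_idx]
        disp = np.zeros_like(p)
        max_overlap = resolve_overlaps(p, radii, pairs[:, 0], pairs[:, 1], disp)
        if max_overlap <= tol:
            return float(max_overlap)
        moved = np.any(disp != 0.0, axis=1)
        pop.pos[alive_idx] = np.clip(p + disp, 0.0, np.asarray(bounds))
        if moved_out is not None:
            moved_out[alive_idx[moved]] = True
    return float(max_overlap)


def grow_cells(pop: CellPopulation, step: int, config: SimulationConfig) -> None:
    """Linear diameter growth from the initial draw up to 14 µm.

    The schedule spans ``growth_start_day``..``growth_end_day`` (the death
    period); diameters are monotone and capped at ``max_diameter``.
    """
    day = step / config.steps_per_day
    span = config.growth_end_day - config.growth_start_day
    frac = 0.0 if span <= 0 else (day - config.growth_start_day) / span
    frac = min(max(frac, 0.0), 1.0)
    target = pop.initial_diameter + (config.max_diameter - pop.initial_diameter) * frac
    np.maximum(pop.diameter, np.minimum(target, config.max_diameter), out=pop.diameter)


def collapse_z(pop: CellPopulation, config: SimulationConfig) -> None:
    """Move each living cell's z a bounded increment toward the mid-plane."""
    zmid = config.extent[2] / 2.0
    dz = np.clip(zmid - pop.pos[:, 2], -config.collapse_rate, config.collapse_rate)
    pop.pos[pop.alive, 2] += dz[pop.alive]


# ---------------------------------------------------------------------------
# run scheduler
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    config: SimulationConfig
    types: TypeTable
    population: CellPopulation
    initial_count: int
    day_log: pd.DataFrame
    cf_end_step: int | None
    steps_run: int
    steady: bool
    grids: list[SubstanceGrid] | None = None
    snapshots: dict[int, pd.DataFrame] = field(default_factory=dict)

    @property
    def death_rate(self) -> float:
        return 1.0 - self.population.n_alive / self.initial_count

    def death_rate_trajectory(self) -> np.ndarray:
        counts = np.concatenate(
            [[self.initial_count], self.day_log["n_alive"].to_numpy()]
        )
        return _metrics.death_rate(counts)

    def per_type_stats(self, min_cells: int = 3) -> pd.DataFrame:
        """Final per-type mosaic statistics inside the analysis window."""
        cfg = self.config
        window = cfg.window
        rows = []
        for t, name in enumerate(self.types.names):
            sel = self.population.alive & (self.population.type_id == t)
            pts = self.population.pos[sel, :2]
            inside = (
                (pts[:, 0] >= window[0]) & (pts[:, 0] <= window[1])
                & (pts[:, 1] >= window[2]) & (pts[:, 1] <= window[3])
            )
            n_in = int(inside.sum())
            ri = np.nan
            if n_in >= min_cells and pts.shape[0] >= min_cells:
                ri = _metrics.regularity_index(pts, window=window)
            mig = _metrics.migration_distances(
                self.population.pos[sel], self.population.birth_pos[sel]
            )
            rows.append(
                {
                    "type_id": t,
                    "name": name,
                    "n_alive": int(sel.sum()),
                    "n_window": n_in,
                    "density_mm2": n_in / cfg.window_area_mm2,
                    "ri": ri,
                    "mean_migration_um": float(mig.mean()) if mig.size else np.nan,
                    "sd_migration_um": float(mig.std(ddof=1)) if mig.size > 1 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def average_ri(self, min_cells: int = 3) -> float:
        """Across-type mean RI (each type weighted equally; finite RIs only)."""
        ri = self.per_type_stats(min_cells=min_cells)["ri"].to_numpy()
        ri = ri[np.isfinite(ri)]
        return float(ri.mean()) if ri.size else np.nan

    def migration_summary(self, survivors_only: bool = True) -> tuple[float, float]:
        pop = self.population
        d = _metrics.migration_distances(
            pop.pos, pop.birth_pos, alive=pop.alive, survivors_only=survivors_only
        )
        return float(d.mean()), float(d.std(ddof=1))


def run(
    config: SimulationConfig,
    types: TypeTable,
    params: "MechanismParams",
    keep_grids: bool = False,
    snapshot_days: Iterable[int] = (),
    progress: bool = False,
) -> RunResult:
    """Execute a full simulation.

    Per step: secretion → diffusion → behaviours (CF until complete, then CD
    then CM) → mechanical relaxation → growth → z-collapse.  Stops early once
    every active behaviour is at steady state (fewer than ``steady_*_frac`` of
    living cells dying/moving per day) when ``stop_on_steady`` is set.
    """
    from .mechanisms import cd_step, cf_step, cm_step  # local import, no cycle at module load

    rng = np.random.default_rng(config.seed)
    pop = initialize_population(config, types, rng)
    initial_count = len(pop)
    params.validate(config.mechanisms)

    shape = config.grid_shape
    grids = [
        SubstanceGrid(
            substance_id=s,
            shape=shape,
            voxel_size=config.voxel_size,
            nu=config.nu,
            mu=config.mu,
            substeps=config.substeps,
            boundary=config.boundary,
            dtype=config.grid_dtype,
        )
        for s in range(types.n_substances)
    ]
    sub_of_type = types.substance_of_type
    target_counts = types.densities / types.densities.sum() * initial_count
    assigned = np.zeros(types.n_types, dtype=np.int64)
    if "CF" not in config.mechanisms:
        assigned = np.bincount(pop.type_id, minlength=types.n_types)

    bounds = config.extent
    mech = config.mechanisms
    cf_active = "CF" in mech
    cf_end_step: int | None = None if cf_active else 0
    day_rows = []
    snapshots: dict[int, pd.DataFrame] = {}
    snapshot_days = set(snapshot_days)

    deaths_today = 0
    movers_today = np.zeros(initial_count, dtype=bool)
    diffs_today = 0
    steady = False
    step = 0

    for step in range(1, config.max_steps + 1):
        alive = pop.alive
        differentiated = alive & (pop.type_id != UNDIFFERENTIATED)

        # 1. secretion by living differentiated cells
        if differentiated.any():
            d_idx = np.flatnonzero(differentiated)
            idx3 = grids[0].voxel_indices(pop.pos[d_idx])
            subs = sub_of_type[pop.type_id[d_idx]]
            for s in range(len(grids)):
                sel = subs == s
                if sel.any():
                    grids[s].secrete_at(idx3[sel], config.secretion_rate)

        # 2. diffusion
        for g in grids:
            g.diffuse_step()

        # 3. behaviours
        if cf_active and cf_end_step is None:
            diffs_today += cf_step(pop, grids, types, params, target_counts, assigned, rng)
            if pop.n_undifferentiated == 0:
                cf_end_step = step
        elif cf_end_step is not None:
            if "CD" in mech:
                deaths_today += cd_step(pop, grids, types, params)
            if "CM" in mech:
                cm_step(pop, grids, types, params, bounds, moved_out=movers_today)

        # 4–6. mechanics, growth, collapse
        relax_mechanics(
            pop, bounds, max_iter=config.relax_iters, tol_frac=config.relax_tol
        )
        grow_cells(pop, step, config)
        collapse_z(pop, config)

        # day boundary bookkeeping
        if step % config.steps_per_day == 0:
            day = step // config.steps_per_day
            n_alive = pop.n_alive
            day_rows.append(
                {
                    "day": day,
                    "step": step,
                    "n_alive": n_alive,
                    "n_undifferentiated": pop.n_undifferentiated,
                    "differentiations": diffs_today,
                    "deaths": deaths_today,
                    "movers": int(movers_today.sum()),
                }
            )
            if day in snapshot_days:
                snapshots[day] = pop.to_dataframe(types.names)
            for g in grids:
                g.check_nonnegative()
            if progress:  # pragma: no cover
                print(f"day {day}: alive={n_alive} undiff={pop.n_undifferentiated} "
                      f"deaths={deaths_today} movers={int(movers_today.sum())}")
            if config.stop_on_steady and cf_end_step is not None:
                cd_ok = ("CD" not in mech) or (
                    deaths_today < config.steady_death_frac * max(n_alive, 1)
                )
                cm_ok = ("CM" not in mech) or (
                    movers_today.sum() < config.steady_move_frac * max(n_alive, 1)
                )
                if cd_ok and cm_ok:
                    steady = True
            deaths_today = 0
            diffs_today = 0
            movers_today[:] = False
            if steady:
                break

    day_log = pd.DataFrame(
        day_rows,
        columns=["day", "step", "n_alive", "n_undifferentiated",
                 "differentiations", "deaths", "movers"],
    )
    return RunResult(
        config=config,
        types=types,
        population=pop,
        initial_count=initial_count,
        day_log=day_log,
        cf_end_step=cf_end_step,
        steps_run=step,
        steady=steady,
        grids=grids if keep_grids else None,
        snapshots=snapshots,
    )
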