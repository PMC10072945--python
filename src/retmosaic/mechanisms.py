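"""The three mosaic-formation behaviours: fate (CF), death (CD), migration (CM).

Every behaviour is homotypic: a cell consults only the substance of its own
type (or, for an undifferentiated cell, the substances of the candidate
types).  Threshold comparisons are strict — a behaviour fires only when the
concentration is *higher than* its threshold.

* CF: a differentiated cell's substance inhibits nearby undifferentiated
  cells from adopting the same type.  An undifferentiated cell attempts a
  fate choice with probability ``differentiation_rate`` per step and adopts
  one non-inhibited type sampled with probability proportional to that
  type's remaining target density (plain target-density weighting is
  available via ``cf_weighting='target'``).
* CD: a differentiated cell removes itself when its own-type concentration
  exceeds its death threshold, thinning homotypic clusters.
* CM: when the own-type concentration exceeds the (lower) migration
  threshold, the cell moves ``migration_step`` µm against the normalized
  in-plane (x, y) gradient of its own substance — short-distance homotypic
  avoidance.  z is owned by the slab collapse, not by CM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import UNDIFFERENTIATED, CellAgent, CellPopulation, TypeTable
from .grids import ConfigurationError, SubstanceGrid

__all__ = [
    "MechanismParams",
    "cf_step",
    "cd_step",
    "cm_step",
    "cf_update",
    "cd_update",
    "cm_update",
]


@dataclass
class MechanismParams:
    """Per-type thresholds and behaviour rates.

    ``death_threshold`` / ``migration_threshold`` are concentration values in
    the substance units of the run (one secretion unit per source per step);
    the migration threshold is always below the death threshold so migration
    is triggered before death.  ``cf_inhibition_threshold`` and
    ``differentiation_rate`` govern the fate mechanism and are calibration
    parameters (chosen so differentiation completes within one simulated
    day); ``migration_step`` is the per-step displacement in µm.
    """

    death_threshold: np.ndarray
    migration_threshold: np.ndarray
    # scalar, or one inhibition threshold per type: dense types need higher
    # thresholds (shorter inhibition radii) than their own target spacing
    cf_inhibition_threshold: float | np.ndarray = 0.003
    migration_step: float = 0.25
    differentiation_rate: float = 0.02
    cf_weighting: str = "remaining"

    def __post_init__(self) -> None:
        self.death_threshold = np.atleast_1d(np.asarray(self.death_threshold, dtype=float))
        self.migration_threshold = np.atleast_1d(
            np.asarray(self.migration_threshold, dtype=float)
        )
        if self.cf_weighting not in ("remaining", "target"):
            raise ConfigurationError("cf_weighting must be 'remaining' or 'target'")

    def validate(self, mechanisms: frozenset[str] = frozenset({"CF", "CD", "CM"})) -> None:
        if "CD" in mechanisms and np.any(self.death_threshold <= 0):
            raise ConfigurationError("death thresholds must be positive")
        if "CM" in mechanisms and np.any(self.migration_threshold <= 0):
            raise ConfigurationError("migration thresholds must be positive")
        if "CD" in mechanisms and "CM" in mechanisms:
            if np.any(self.migration_threshold >= self.death_threshold):
                raise ConfigurationError(
                    "migration threshold must be below the death threshold for every type"
                )
        if "CF" in mechanisms and np.any(np.asarray(self.cf_inhibition_threshold) <= 0):
            raise ConfigurationError("cf_inhibition_threshold must be positive")


# ---------------------------------------------------------------------------
# vectorized per-step updates (the path used by the scheduler)
# ---------------------------------------------------------------------------

def cf_step(
    pop: CellPopulation,
    grids: list[SubstanceGrid],
    types: TypeTable,
    params: MechanismParams,
    target_counts: np.ndarray,
    assigned: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """One fate-determination step over all undifferentiated living cells.

    Returns the number of cells that differentiated.  Cells whose candidate
    types are all inhibited stay undifferentiated this step.
    """
    cand = np.flatnonzero(pop.alive & (pop.type_id == UNDIFFERENTIATED))
    if cand.size == 0:
        return 0
    attempt = rng.random(cand.size) < params.differentiation_rate
    cand = cand[attempt]
    if cand.size == 0:
        return 0
    idx3 = grids[0].voxel_indices(pop.pos[cand])
    n_types = types.n_types
    conc = np.empty((n_types, cand.size), dtype=np.float64)
    for t in range(n_types):
        conc[t] = grids[types.substance_of_type[t]].values_at(idx3)
    thr = np.asarray(params.cf_inhibition_threshold, dtype=float)
    thr = thr[:, None] if thr.ndim else thr  # scalar or per-type thresholds
    allowed = conc <= thr  # strict > inhibits

    if params.cf_weighting == "remaining":
        w = np.maximum(target_counts - assigned, 0.0)
        if not np.any(w > 0):
            w = target_counts.astype(float)
    else:
        w = target_counts.astype(float)
    # per-cell weighted choice among allowed types via the Gumbel-max trick
    with np.errstate(divide="ignore"):
        logw = np.log(w)[:, None]
    gumbel = -np.log(-np.log(rng.random((n_types, cand.size))))
    score = np.where(allowed & (w[:, None] > 0), logw + gumbel, -np.inf)
    # fall back to plain target weights for cells whose remaining-weight
    # choices are exhausted but that still have non-inhibited types
    stuck = ~np.isfinite(score.max(axis=0)) & allowed.any(axis=0)
    if params.cf_weighting == "remaining" and np.any(stuck):
        with np.errstate(divide="ignore"):
            logw_t = np.log(target_counts.astype(float))[:, None]
        score[:, stuck] = np.where(
            allowed[:, stuck], logw_t + gumbel[:, stuck], -np.inf
        )
    choice = score.argmax(axis=0)
    ok = np.isfinite(score.max(axis=0))
    chosen_cells = cand[ok]
    chosen_types = choice[ok]
    pop.type_id[chosen_cells] = chosen_types
    if chosen_types.size:
        assigned += np.bincount(chosen_types, minlength=n_types)
    return int(chosen_cells.size)


def cd_step(
    pop: CellPopulation,
    grids: list[SubstanceGrid],
    types: TypeTable,
    params: MechanismParams,
) -> int:
    """One death step: mark cells whose own-type concentration is above threshold."""
    sel = np.flatnonzero(pop.alive & (pop.type_id != UNDIFFERENTIATED))
    if sel.size == 0:
        return 0
    idx3 = grids[0].voxel_indices(pop.pos[sel])
    tid = pop.type_id[sel]
    conc = np.empty(sel.size, dtype=np.float64)
    subs = types.substance_of_type[tid]
    for s in np.unique(subs):
        m = subs == s
        conc[m] = grids[s].values_at(idx3[m])
    dead = conc > params.death_threshold[tid]
    pop.alive[sel[dead]] = False
    return int(dead.sum())


def cm_step(
    pop: CellPopulation,
    grids: list[SubstanceGrid],
    types: TypeTable,
    params: MechanismParams,
    bounds: tuple[float, float, float],
    moved_out: np.ndarray | None = None,
) -> int:
    """One migration step: super-threshold cells move down their own gradient.

    The displacement is ``migration_step`` µm along the negative normalized
    in-plane gradient; cells with a zero in-plane gradient do not move.
    """
    sel = np.flatnonzero(pop.alive & (pop.type_id != UNDIFFERENTIATED))
    if sel.size == 0:
        return 0
    idx3 = grids[0].voxel_indices(pop.pos[sel])
    tid = pop.type_id[sel]
    subs = types.substance_of_type[tid]
    n_moved = 0
    for s in np.unique(subs):
        m = subs == s
        conc = grids[s].values_at(idx3[m])
        hot = conc > params.migration_threshold[tid[m]]
        if not hot.any():
            continue
        cells = sel[m][hot]
        grad = grids[s]._gradient(idx3[m][hot])[:, :2]
        norm = np.hypot(grad[:, 0], grad[:, 1])
        movable = norm > 0.0
        cells = cells[movable]
        if cells.size == 0:
            continue
        unit = grad[movable] / norm[movable, None]
        pop.pos[cells, 0] = np.clip(
            pop.pos[cells, 0] - params.migration_step * unit[:, 0], 0.0, bounds[0]
        )
        pop.pos[cells, 1] = np.clip(
            pop.pos[cells, 1] - params.migration_step * unit[:, 1], 0.0, bounds[1]
        )
        if moved_out is not None:
            moved_out[cells] = True
        n_moved += int(cells.size)
    return n_moved


# ---------------------------------------------------------------------------
# single-cell wrappers (spec-level operations; used by tests and docs)
# ---------------------------------------------------------------------------

def _one_cell_pop(cell: CellAgent) -> CellPopulation:
    pop = CellPopulation(
        pos=cell.position[None, :].astype(float),
        diameter=np.array([cell.diameter]),
        type_id=np.array([cell.type_id]),
    )
    pop.birth_pos = np.asarray(cell.birth_position, dtype=float)[None, :].copy()
    pop.alive[0] = cell.alive
    pop.layer[0] = cell.layer
    return pop


def cf_update(
    cell: CellAgent,
    grids: list[SubstanceGrid],
    types: TypeTable,
    params: MechanismParams,
    rng: np.random.Generator,
    assigned: np.ndarray | None = None,
    total_cells: int = 1,
) -> CellAgent:
    """Fate update for a single undifferentiated cell (see :func:`cf_step`)."""
    if types.n_types == 0:
        raise ConfigurationError("empty cell-type catalogue")
    if not cell.alive or cell.type_id != UNDIFFERENTIATED:
        return cell
    pop = _one_cell_pop(cell)
    targets = types.densities / types.densities.sum() * max(total_cells, 1)
    if assigned is None:
        assigned = np.zeros(types.n_types, dtype=np.int64)
    cf_step(pop, grids, types, params, targets, assigned, rng)
    return replace(cell, type_id=int(pop.type_id[0]))


def cd_update(
    cell: CellAgent,
    grids: list[SubstanceGrid],
    types: TypeTable,
    params: MechanismParams,
) -> CellAgent:
    """Death update for a single differentiated cell (see :func:`cd_step`)."""
    if not cell.alive or cell.type_id == UNDIFFERENTIATED:
        return cell
    pop = _one_cell_pop(cell)
    cd_step(pop, grids, types, params)
    return replace(cell, alive=bool(pop.alive[0]))


def cm_update(
    cell: CellAgent,
    grids: list[SubstanceGrid],
    types: TypeTable,
    params: MechanismParams,
    bounds: tuple[float, float, float],
) -> CellAgent:
    """Migration update for a single differentiated cell (see :func:`cm_step`)."""
    if not cell.alive or cell.type_id == UNDIFFERENTIATED:
        return cell
    pop = _one_cell_pop(cell)
    cm_step(pop, grids, types, params, bounds)
    return replace(cell, position=pop.pos[0].copy())
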