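"""Behaviour modules: fate inhibition, threshold death, chemorepulsion."""

import numpy as np
import pytest

from retmosaic import (
    CellAgent,
    CellPopulation,
    ConfigurationError,
    MechanismParams,
    SubstanceGrid,
    TypeTable,
    UNDIFFERENTIATED,
    cd_update,
    cf_update,
    cm_update,
)
from retmosaic.mechanisms import cd_step, cf_step, cm_step

BOUNDS = (100.0, 100.0, 22.0)
SHAPE = (25, 25, 6)


def make_grids(n):
    return [SubstanceGrid(s, SHAPE, voxel_size=4.0) for s in range(n)]


def cell_at(x=50.0, y=50.0, z=11.0, type_id=0):
    p = np.array([x, y, z])
    return CellAgent(id=0, position=p, birth_position=p.copy(), diameter=8.0,
                     type_id=type_id)


def params_for(n, death=2.0, migration=1.0):
    return MechanismParams(
        death_threshold=np.full(n, death), migration_threshold=np.full(n, migration)
    )


class TestCellDeath:
    def test_threshold_is_strict(self):
        grids = make_grids(1)
        types = TypeTable(names=["a"], densities=np.array([100.0]))
        p = params_for(1, death=2.0)
        grids[0].secrete((50.0, 50.0, 11.0), 2.0)
        assert cd_update(cell_at(), grids, types, p).alive  # exactly at threshold
        grids[0].secrete((50.0, 50.0, 11.0), 0.5)
        assert not cd_update(cell_at(), grids, types, p).alive  # above threshold

    def test_zero_concentration_survives(self):
        grids = make_grids(1)
        types = TypeTable(names=["a"], densities=np.array([100.0]))
        assert cd_update(cell_at(), grids, types, params_for(1)).alive

    def test_only_own_type_substance_consulted(self):
        types = TypeTable(names=["a", "b"], densities=np.array([100.0, 100.0]))
        p = params_for(2, death=2.0)
        grids = make_grids(2)
        grids[1].secrete((50.0, 50.0, 11.0), 99.0)  # massive heterotypic signal
        assert cd_update(cell_at(type_id=0), grids, types, p).alive

    def test_undifferentiated_cells_exempt(self):
        grids = make_grids(1)
        grids[0].secrete((50.0, 50.0, 11.0), 99.0)
        types = TypeTable(names=["a"], densities=np.array([100.0]))
        cell = cell_at(type_id=UNDIFFERENTIATED)
        assert cd_update(cell, grids, types, params_for(1)).alive


class TestCellMigration:
    def test_below_threshold_no_move(self):
        grids = make_grids(1)
        types = TypeTable(names=["a"], densities=np.array([100.0]))
        cell = cell_at()
        out = cm_update(cell, grids, types, params_for(1, migration=1.0), BOUNDS)
        np.testing.assert_array_equal(out.position, cell.position)

    def test_moves_away_from_point_source(self):
        grids = make_grids(1)
        types = TypeTable(names=["a"], densities=np.array([100.0]))
        # source east of the cell; saturate the cell's own voxel above threshold
        for _ in range(30):
            grids[0].secrete((58.0, 50.0, 11.0), 1.0)
            grids[0].diffuse_step()
        p = params_for(1, migration=grids[0].concentration_at((50.0, 50.0, 11.0)) * 0.5)
        out = cm_update(cell_at(), grids, types, p, BOUNDS)
        assert out.position[0] < 50.0  # moved west
        assert out.position[1] == pytest.approx(50.0)
        assert out.position[2] == 11.0  # z untouched by migration
        assert np.linalg.norm(out.position[:2] - [50, 50]) == pytest.approx(
            p.migration_step
        )

    def test_zero_gradient_no_move(self):
        grids = make_grids(1)
        grids[0].conc = np.full(SHAPE, 5.0)  # uniform: above threshold, flat
        types = TypeTable(names=["a"], densities=np.array([100.0]))
        out = cm_update(cell_at(), grids, types, params_for(1, migration=1.0), BOUNDS)
        np.testing.assert_array_equal(out.position, [50.0, 50.0, 11.0])

    def test_heterotypic_field_ignored(self):
        types = TypeTable(names=["a", "b"], densities=np.array([100.0, 100.0]))
        grids = make_grids(2)
        for _ in range(30):
            grids[1].secrete((58.0, 50.0, 11.0), 1.0)
            grids[1].diffuse_step()
        out = cm_update(cell_at(type_id=0), grids, types, params_for(2), BOUNDS)
        np.testing.assert_array_equal(out.position, [50.0, 50.0, 11.0])

    def test_two_homotypic_cells_repel_over_time(self):
        types = TypeTable(names=["a"], densities=np.array([100.0]))
        grids = make_grids(1)
        pos = np.array([[46.0, 50, 11], [54.0, 50, 11]])
        pop = CellPopulation(pos, np.full(2, 8.0), type_id=np.zeros(2, dtype=int))
        p = params_for(1, migration=0.05)
        sep0 = pop.pos[1, 0] - pop.pos[0, 0]
        for _ in range(120):
            idx = grids[0].voxel_indices(pop.pos)
            grids[0].secrete_at(idx, 1.0)
            grids[0].diffuse_step()
            cm_step(pop, grids, types, p, BOUNDS)
        assert pop.pos[1, 0] - pop.pos[0, 0] > sep0 + 5.0


class TestCellFate:
    def _setup(self, n_types=2):
        types = TypeTable(
            names=[f"t{i}" for i in range(n_types)],
            densities=np.full(n_types, 100.0),
        )
        return types, make_grids(n_types)

    def test_no_inhibition_adopts_proportionally(self):
        types = TypeTable(names=["a", "b"], densities=np.array([300.0, 100.0]))
        grids = make_grids(2)
        n = 4000
        rng = np.random.default_rng(0)
        pop = CellPopulation(
            np.column_stack([rng.uniform(0, 100, n), rng.uniform(0, 100, n),
                             np.full(n, 11.0)]),
            np.full(n, 8.0),
        )
        p = params_for(2)
        p.differentiation_rate = 1.0
        targets = types.densities / types.densities.sum() * n
        assigned = np.zeros(2, dtype=np.int64)
        # weights follow the *remaining* target, so after full assignment the
        # split matches the 3:1 target densities almost exactly
        cf_step(pop, grids, types, p, targets, assigned, rng)
        frac_a = (pop.type_id == 0).mean()
        assert frac_a == pytest.approx(0.75, abs=0.02)

    def test_forced_choice_when_all_but_one_inhibited(self):
        types, grids = self._setup(3)
        for s in (0, 2):
            grids[s].secrete((50.0, 50.0, 11.0), 10.0)  # types 0 and 2 inhibited
        p = params_for(3)
        p.differentiation_rate = 1.0
        rng = np.random.default_rng(1)
        cell = cf_update(cell_at(type_id=UNDIFFERENTIATED), grids, types, p, rng)
        assert cell.type_id == 1

    def test_two_type_toy_inhibition(self):
        types, grids = self._setup(2)
        grids[0].secrete((50.0, 50.0, 11.0), 1.0)  # type A above cf threshold
        p = params_for(2)
        p.differentiation_rate = 1.0
        rng = np.random.default_rng(2)
        cell = cf_update(cell_at(type_id=UNDIFFERENTIATED), grids, types, p, rng)
        assert cell.type_id == 1

    def test_fully_inhibited_cell_stays_undifferentiated(self):
        types, grids = self._setup(2)
        for g in grids:
            g.secrete((50.0, 50.0, 11.0), 10.0)
        p = params_for(2)
        p.differentiation_rate = 1.0
        rng = np.random.default_rng(3)
        cell = cf_update(cell_at(type_id=UNDIFFERENTIATED), grids, types, p, rng)
        assert cell.type_id == UNDIFFERENTIATED

    def test_empty_catalogue_rejected(self):
        types = TypeTable(names=[], densities=np.array([]))
        with pytest.raises((ConfigurationError, ValueError)):
            cf_update(cell_at(type_id=UNDIFFERENTIATED), [], types,
                      params_for(1), np.random.default_rng(0))


class TestParamValidation:
    def test_migration_must_be_below_death(self):
        p = MechanismParams(
            death_threshold=np.array([2.0, 2.0]),
            migration_threshold=np.array([1.9, 2.0]),
        )
        with pytest.raises(ConfigurationError):
            p.validate(frozenset({"CD", "CM"}))
        p.validate(frozenset({"CD"}))  # ordering only matters when both active

    def test_thresholds_positive(self):
        p = MechanismParams(
            death_threshold=np.array([0.0]), migration_threshold=np.array([-1.0])
        )
        with pytest.raises(ConfigurationError):
            p.validate(frozenset({"CD"}))
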