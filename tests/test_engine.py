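"""Cell engine: initialization, mechanics, growth, collapse, scheduler."""

import dataclasses

import numpy as np
import pytest

from retmosaic import (
    CellPopulation,
    ConfigurationError,
    MechanismParams,
    SimulationConfig,
    TypeTable,
    UNDIFFERENTIATED,
    collapse_z,
    grow_cells,
    initialize_population,
    relax_mechanics,
    run,
)


def make_pop(positions, diameter=8.0):
    pos = np.asarray(positions, dtype=float)
    return CellPopulation(pos, np.full(len(pos), float(diameter)))


def brute_force_max_overlap(pop):
    idx = np.flatnonzero(pop.alive)
    worst = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            d = np.linalg.norm(pop.pos[i] - pop.pos[j])
            worst = max(worst, (pop.diameter[i] + pop.diameter[j]) / 2 - d)
    return worst


class TestInitialization:
    def test_expected_count_from_density(self, small_config, two_type_table, rng):
        pop = initialize_population(small_config, two_type_table, rng)
        # 3000 cells/mm2 in a (200 + 2*60) um square
        assert len(pop) == round(3000 * 0.32**2)
        ex, ey, ez = small_config.extent
        assert pop.pos[:, 0].max() <= ex and pop.pos[:, 2].max() <= ez
        assert np.all((pop.diameter >= 7.0) & (pop.diameter <= 8.0))

    def test_cf_enabled_starts_undifferentiated(self, small_config, two_type_table, rng):
        cfg = dataclasses.replace(small_config, mechanisms=frozenset({"CF"}))
        pop = initialize_population(cfg, two_type_table, rng)
        assert np.all(pop.type_id == UNDIFFERENTIATED)

    def test_pre_typed_counts_match_densities(self, small_config, two_type_table, rng):
        pop = initialize_population(small_config, two_type_table, rng)
        counts = np.bincount(pop.type_id, minlength=2)
        ideal = len(pop) * two_type_table.densities / two_type_table.densities.sum()
        assert np.all(np.abs(counts - ideal) <= 1.0)  # largest-remainder rounding

    def test_zero_cell_density_rejected(self, small_config, two_type_table, rng):
        cfg = dataclasses.replace(small_config, initial_density=1e-6)
        with pytest.raises(ConfigurationError):
            initialize_population(cfg, two_type_table, rng)

    def test_single_cell_is_valid(self, two_type_table, rng):
        cfg = SimulationConfig(initial_density=15.0, mechanisms=frozenset()).scaled(
            core=200, margin=60, voxel_size=4.0
        )
        pop = initialize_population(cfg, two_type_table, rng)
        assert len(pop) >= 1


class TestMechanics:
    def test_coincident_cells_separate(self):
        pop = make_pop([[50.0, 50, 10], [50.0, 50, 10]])
        relax_mechanics(pop, (100, 100, 22), max_iter=40)
        d = np.linalg.norm(pop.pos[0] - pop.pos[1])
        assert d >= 8.0 * (1 - 0.01)

    def test_distant_cells_untouched(self):
        pop = make_pop([[10.0, 10, 10], [30.0, 10, 10]])
        before = pop.pos.copy()
        relax_mechanics(pop, (100, 100, 22))
        np.testing.assert_array_equal(pop.pos, before)

    def test_packed_box_relaxes_below_tolerance(self, rng):
        pts = rng.uniform(100, 130, (100, 3)) * [1, 1, 22 / 130]
        pop = make_pop(pts, diameter=8.0)
        for _ in range(60):
            worst = relax_mechanics(pop, (300, 300, 22), max_iter=10)
        assert brute_force_max_overlap(pop) == pytest.approx(worst, abs=1e-9)
        assert worst <= 0.5  # best-effort packing; cells cannot fully separate in z=22

    def test_dead_cells_ignored(self):
        pop = make_pop([[50.0, 50, 10], [50.0, 50, 10]])
        pop.alive[1] = False
        before = pop.pos.copy()
        relax_mechanics(pop, (100, 100, 22))
        np.testing.assert_array_equal(pop.pos, before)


class TestGrowthAndCollapse:
    def test_growth_schedule(self, small_config):
        pop = make_pop([[50.0, 50, 10]], diameter=7.5)
        grow_cells(pop, 0, small_config)
        assert pop.diameter[0] == 7.5
        grow_cells(pop, int(3.5 * 160), small_config)
        assert 7.5 < pop.diameter[0] < 14.0
        grow_cells(pop, 160 * 10, small_config)
        assert pop.diameter[0] == 14.0
        # monotone: revisiting an earlier step never shrinks the diameter
        grow_cells(pop, 0, small_config)
        assert pop.diameter[0] == 14.0

    def test_collapse_moves_toward_midplane(self, small_config):
        zmid = small_config.extent[2] / 2
        pop = make_pop([[50.0, 50, 20.0]])
        for _ in range(120):
            collapse_z(pop, small_config)
        assert abs(pop.pos[0, 2] - zmid) < 0.2
        z_before = pop.pos[0, 2]
        collapse_z(pop, small_config)
        assert abs(pop.pos[0, 2] - zmid) <= abs(z_before - zmid)


class TestRunScheduler:
    def _params(self, n=2):
        return MechanismParams(
            death_threshold=np.full(n, 5.0), migration_threshold=np.full(n, 4.0)
        )

    def test_no_mechanisms_no_deaths_no_types_change(self, small_config, two_type_table):
        res = run(small_config, two_type_table, self._params())
        assert res.population.n_alive == res.initial_count
        assert res.day_log["deaths"].sum() == 0
        counts = np.bincount(res.population.type_id, minlength=2)
        assert counts.sum() == res.initial_count

    def test_deterministic_given_seed(self, small_config, two_type_table):
        cfg = dataclasses.replace(small_config, days=1)
        r1 = run(cfg, two_type_table, self._params())
        r2 = run(cfg, two_type_table, self._params())
        np.testing.assert_array_equal(r1.population.pos, r2.population.pos)
        np.testing.assert_array_equal(r1.population.type_id, r2.population.type_id)

    def test_cell_count_never_increases_and_ids_stable(self, small_config, two_type_table):
        res = run(small_config, two_type_table, self._params())
        alive = res.day_log["n_alive"].to_numpy()
        assert np.all(np.diff(alive) <= 0)
        assert len(res.population) == res.initial_count  # dead cells keep their record
        assert np.array_equal(np.unique(res.population.ids), np.sort(res.population.ids))

    def test_z_spread_shrinks_into_monolayer(self, small_config, two_type_table):
        rng = np.random.default_rng(small_config.seed)
        z0 = initialize_population(small_config, two_type_table, rng).pos[:, 2].std()
        res = run(dataclasses.replace(small_config, days=2), two_type_table, self._params())
        assert res.population.pos[:, 2].std() < z0

    def test_snapshot_dataframe_round_trip(self, small_config, two_type_table):
        res = run(dataclasses.replace(small_config, days=1), two_type_table,
                  self._params(), snapshot_days=(1,))
        df = res.snapshots[1]
        assert list(df.columns) == [
            "id", "type_name", "x_um", "y_um", "z_um", "diameter_um", "alive", "layer"
        ]
        assert len(df) == res.initial_count
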