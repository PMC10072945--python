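import numpy as np
import pytest

from retmosaic import SimulationConfig, TypeTable
from retmosaic.rgc import CellTypeSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_catalogue():
    """Three-type catalogue with the standard 0.35 final/start ratio."""

    def row(i, name, start, d):
        return CellTypeSpec(
            type_id=i, name=name, group="on",
            start_density=start, final_density=round(start * 0.35),
            death_threshold_D=d, death_threshold_FD=d,
            death_threshold_FDM=d, migration_threshold_FDM=d * 0.995,
        )

    return [row(0, "toy_a", 600.0, 2.05), row(1, "toy_b", 300.0, 2.02),
            row(2, "toy_c", 100.0, 1.99)]


@pytest.fixture()
def small_config():
    """A fast, small slab configuration for engine-level tests."""
    return SimulationConfig(
        initial_density=3000.0, mechanisms=frozenset(), condition="D", seed=7,
    ).scaled(core=200.0, margin=60.0, voxel_size=4.0)


@pytest.fixture()
def two_type_table():
    return TypeTable(names=["a", "b"], densities=np.array([200.0, 100.0]))
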