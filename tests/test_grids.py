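"""Diffusion lattice: stencil correctness, conservation, queries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retmosaic import ConfigurationError, OutOfBoundsError, SubstanceGrid
from retmosaic.grids import steady_self_concentration


def naive_reference_step(u, alpha, mu, boundary):
    """Independent triple-loop implementation of one diffusion update."""
    nx, ny, nz = u.shape
    out = np.zeros_like(u)

    def nb(i, j, k, c):
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
            return u[i, j, k]
        return c if boundary == "reflecting" else 0.0

    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = u[i, j, k]
                # neighbour sum ordered z, y, x to match the engine's
                # storage-order arithmetic bit-for-bit
                lap = (
                    nb(i, j, k + 1, c) + nb(i, j, k - 1, c)
                    + nb(i, j + 1, k, c) + nb(i, j - 1, k, c)
                    + nb(i + 1, j, k, c) + nb(i - 1, j, k, c)
                    - 6.0 * c
                )
                out[i, j, k] = (c + alpha * lap) * (1.0 - mu)
    return out


@pytest.mark.parametrize("boundary", ["reflecting", "absorbing"])
@pytest.mark.parametrize("mu", [0.0, 0.05])
def test_stencil_matches_naive_triple_loop(boundary, mu, rng):
    grid = SubstanceGrid("s", (7, 6, 5), voxel_size=4.0, nu=1.5, mu=mu,
                         substeps=1, boundary=boundary)
    field = rng.random((7, 6, 5))
    grid.conc = field
    expected = field.copy()
    for _ in range(4):
        expected = naive_reference_step(expected, grid.alpha, mu, boundary)
        grid.diffuse_step()
    np.testing.assert_array_equal(grid.conc, expected)


def test_single_voxel_spread_hand_example():
    # alpha = 0.1: centre keeps 1-6*alpha = 0.4, each face neighbour gets 0.1
    grid = SubstanceGrid("s", (5, 5, 5), voxel_size=2.0, nu=0.4, substeps=1)
    assert grid.alpha == pytest.approx(0.1)
    grid.conc[2, 2, 2] = 3.0
    grid.diffuse_step()
    assert grid.conc[2, 2, 2] == pytest.approx(0.4 * 3.0)
    for idx in [(1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1), (2, 2, 3)]:
        assert grid.conc[idx] == pytest.approx(0.1 * 3.0)
    assert grid.total_mass() == pytest.approx(3.0)


def test_uniform_field_is_fixed_point_and_zero_stays_zero():
    grid = SubstanceGrid("s", (6, 6, 6), voxel_size=2.0)
    grid.diffuse_step()
    assert grid.total_mass() == 0.0
    grid.conc = np.full((6, 6, 6), 2.5)
    grid.diffuse_step()
    np.testing.assert_allclose(grid.conc, 2.5, rtol=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_mass_conservation_reflecting(seed):
    grid = SubstanceGrid("s", (6, 5, 4), voxel_size=2.0, boundary="reflecting")
    field = np.random.default_rng(seed).random((6, 5, 4))
    grid.conc = field
    before = grid.total_mass()
    grid.diffuse_step()
    assert abs(grid.total_mass() - before) <= 1e-9 * before


def test_decay_scales_total_mass_exactly():
    mu = 0.125
    grid = SubstanceGrid("s", (6, 6, 4), voxel_size=2.0, nu=0.5, mu=mu,
                         substeps=1, boundary="reflecting")
    grid.conc = np.random.default_rng(3).random((6, 6, 4))
    before = grid.total_mass()
    grid.diffuse_step()
    assert grid.total_mass() == pytest.approx(before * (1 - mu), rel=1e-12)


def test_absorbing_boundary_loses_mass():
    grid = SubstanceGrid("s", (5, 5, 5), voxel_size=2.0, boundary="absorbing")
    grid.conc[0, 2, 2] = 1.0
    grid.diffuse_step()
    assert grid.total_mass() < 1.0


def test_point_source_field_symmetric():
    grid = SubstanceGrid("s", (9, 9, 9), voxel_size=2.0)
    grid.conc[4, 4, 4] = 1.0
    for _ in range(5):
        grid.diffuse_step()
    c = grid.conc
    for perm in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]:
        np.testing.assert_array_equal(c, np.transpose(c, perm))
    for ax in range(3):
        np.testing.assert_array_equal(c, np.flip(c, axis=ax))


def test_stability_enforced_at_construction():
    with pytest.raises(ConfigurationError):
        SubstanceGrid("s", (5, 5, 5), voxel_size=2.0, nu=2.0, substeps=1)  # alpha=0.5


def test_secretion_examples():
    grid = SubstanceGrid("s", (10, 10, 5), voxel_size=2.0)
    grid.secrete((5.0, 5.0, 5.0), 1.0)
    assert grid.conc[2, 2, 2] == 1.0
    grid.secrete((5.0, 5.0, 5.0), 0.0)  # amount 0: unchanged
    assert grid.total_mass() == 1.0
    grid.secrete((5.9, 4.1, 5.5), 1.0)  # same voxel: additive
    assert grid.conc[2, 2, 2] == 2.0
    with pytest.raises(OutOfBoundsError):
        grid.secrete((100.0, 0.0, 0.0), 1.0)


def test_concentration_lookup_is_voxel_granular():
    grid = SubstanceGrid("s", (10, 10, 5), voxel_size=2.0)
    grid.conc[3, 3, 1] = 2.5
    assert grid.concentration_at((7.0, 7.0, 3.0)) == 2.5
    # just across the voxel boundary: the neighbour's (zero) value
    assert grid.concentration_at((8.01, 7.0, 3.0)) == 0.0
    assert grid.concentration_at((1.0, 1.0, 1.0)) == 0.0


def test_gradient_examples():
    grid = SubstanceGrid("s", (8, 8, 4), voxel_size=2.0)
    ramp = np.broadcast_to(np.arange(8)[:, None, None], (8, 8, 4)).astype(float)
    grid.conc = ramp
    g = grid.gradient_at((7.0, 7.0, 3.0))
    np.testing.assert_allclose(g, [1 / 2.0, 0.0, 0.0])
    grid.conc = np.full((8, 8, 4), 1.0)
    np.testing.assert_allclose(grid.gradient_at((7.0, 7.0, 3.0)), 0.0)
    # gradient at a face neighbour of a point source points toward the source
    grid.conc = np.zeros((8, 8, 4))
    grid.conc[4, 4, 2] = 1.0
    g = grid.gradient_at((11.0, 9.0, 5.0))  # voxel (5,4,2), east of source
    assert g[0] < 0.0 and g[1] == 0.0


def test_negative_concentration_detected():
    grid = SubstanceGrid("s", (4, 4, 4), voxel_size=2.0)
    grid.conc[1, 1, 1] = -0.5
    with pytest.raises(RuntimeError, match="negative concentration"):
        grid.check_nonnegative()


def test_isolated_source_reaches_steady_state():
    u200 = steady_self_concentration(voxel_size=4.0, slab_z=24.0, steps=250)
    u400 = steady_self_concentration(voxel_size=4.0, slab_z=24.0, steps=450)
    assert u200 == pytest.approx(u400, rel=1e-3)
    assert 0.5 < u400 < 2.0
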