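"""Per-cell-type extracellular substance fields on a regular 3D voxel grid.

Each differentiated cell type secretes its own diffusible substance into the
voxel containing the cell centre; the field evolves by the explicit
central-difference scheme and cells read back concentrations and gradients as
the developmental cue for fate inhibition, death, and chemorepulsive
migration.

Concentrations are in arbitrary units (one secretion event raises the source
voxel by ``secretion amount`` per simulation step); lengths are in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import diffuse_substep_padded

__all__ = [
    "SubstanceGrid",
    "ConfigurationError",
    "OutOfBoundsError",
    "steady_self_concentration",
    "lateral_kernel_profile",
    "kernel_value",
]


class ConfigurationError(ValueError):
    """Raised for invalid grid / simulation configuration."""


class OutOfBoundsError(IndexError):
    """Raised when a queried position falls outside the voxel lattice."""


MAX_STABLE_ALPHA = 1.0 / 6.0  # explicit 7-point scheme, 3D


def default_substeps(nu: float, voxel_size: float) -> int:
    """Number of diffusion sub-steps per simulation step.

    Chosen so each sub-step has alpha = nu*dt/dx^2 <= 1/8 while the *total*
    diffusion per simulation step matches nu with a unit step duration.
    """
    return max(1, int(np.ceil(8.0 * nu / voxel_size**2)))


@dataclass
class SubstanceGrid:
    """Concentration lattice of one substance.

    Parameters
    ----------
    substance_id : identifier of the secreting cell type.
    shape : lattice dimensions (nx, ny, nz).
    voxel_size : cubic voxel edge length, µm.
    nu : diffusion coefficient, µm²/step.
    mu : decay constant per sub-step update (dimensionless).
    substeps : diffusion updates per simulation step; ``None`` selects the
        largest stable sub-step (alpha = 1/8 convention).
    boundary : "reflecting" (zero-flux mirror; conserves mass when mu=0) or
        "absorbing" (outside voxels held at zero; substance leaks away).
    origin : world coordinate of the (0,0,0) voxel corner, µm.
    """

    substance_id: int | str
    shape: tuple[int, int, int]
    voxel_size: float = 2.0
    nu: float = 2.0
    mu: float = 0.0
    substeps: int | None = None
    boundary: str = "reflecting"
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    dtype: str = "float64"  # "float32" halves memory traffic for large runs

    def __post_init__(self) -> None:
        if self.boundary not in ("reflecting", "absorbing"):
            raise ConfigurationError(f"unknown boundary condition {self.boundary!r}")
        if self.substeps is None:
            self.substeps = default_substeps(self.nu, self.voxel_size)
        if self.substeps < 1:
            raise ConfigurationError("substeps must be >= 1")
        if not 0.0 <= self.mu < 1.0:
            raise ConfigurationError("decay constant mu must lie in [0, 1)")
        self.dt = 1.0 / self.substeps
        self.alpha = self.nu * self.dt / self.voxel_size**2
        if self.alpha > MAX_STABLE_ALPHA + 1e-12:
            raise ConfigurationError(
                f"stability violated: nu*dt/dx^2 = {self.alpha:.4f} > 1/6 "
                f"(nu={self.nu}, dt={self.dt}, voxel={self.voxel_size} µm); "
                "increase substeps or the voxel size"
            )
        self.origin = np.asarray(self.origin, dtype=float)
        nx, ny, nz = self.shape
        # concentrations live inside a ghost-padded buffer kept z-outer for
        # stencil speed; `conc` is a writable (nx, ny, nz) view
        self._pad = np.zeros((nz + 2, ny + 2, nx + 2), dtype=np.dtype(self.dtype))
        self._pad_b = np.zeros_like(self._pad)
        self._active = False  # becomes True once any substance is present

    @property
    def conc(self) -> np.ndarray:
        """The (nx, ny, nz) concentration lattice (a writable view)."""
        return self._pad[1:-1, 1:-1, 1:-1].transpose(2, 1, 0)

    @conc.setter
    def conc(self, values) -> None:
        self._pad[1:-1, 1:-1, 1:-1].transpose(2, 1, 0)[...] = values
        self._active = True

    # ------------------------------------------------------------------ update
    def diffuse_step(self) -> None:
        """Apply ``substeps`` explicit diffusion updates (one simulation step)."""
        if not self._active:
            if not np.any(self._pad):
                return  # nothing secreted yet: the all-zero field is a fixed point
            self._active = True
        reflecting = self.boundary == "reflecting"
        for _ in range(self.substeps):
            pad = self._pad
            if reflecting:  # mirror the boundary planes into the ghosts
                pad[0, 1:-1, 1:-1] = pad[1, 1:-1, 1:-1]
                pad[-1, 1:-1, 1:-1] = pad[-2, 1:-1, 1:-1]
                pad[1:-1, 0, 1:-1] = pad[1:-1, 1, 1:-1]
                pad[1:-1, -1, 1:-1] = pad[1:-1, -2, 1:-1]
                pad[1:-1, 1:-1, 0] = pad[1:-1, 1:-1, 1]
                pad[1:-1, 1:-1, -1] = pad[1:-1, 1:-1, -2]
            diffuse_substep_padded(pad, self._pad_b, self.alpha, self.mu)
            self._pad, self._pad_b = self._pad_b, self._pad

    def secrete(self, position, amount: float = 1.0) -> None:
        """Add ``amount`` to the voxel containing ``position`` (µm)."""
        i, j, k = self.voxel_index(position)
        self.conc[i, j, k] += amount
        self._active = True

    def secrete_many(self, indices: np.ndarray, amount: float = 1.0) -> None:
        """Point-source secretion for many cells given flat voxel indices."""
        np.add.at(self.conc, np.unravel_index(indices, self.shape), amount)
        self._active = True

    def secrete_at(self, idx3: np.ndarray, amount: float = 1.0) -> None:
        """Point-source secretion for many cells given (n,3) voxel indices."""
        np.add.at(self.conc, (idx3[:, 0], idx3[:, 1], idx3[:, 2]), amount)
        self._active = True

    def values_at(self, idx3: np.ndarray) -> np.ndarray:
        """Concentrations at (n,3) voxel indices."""
        return self.conc[idx3[:, 0], idx3[:, 1], idx3[:, 2]]

    # ----------------------------------------------------------------- queries
    def voxel_index(self, position) -> tuple[int, int, int]:
        idx = self.voxel_indices(np.asarray(position, dtype=float)[None, :])[0]
        return int(idx[0]), int(idx[1]), int(idx[2])

    def voxel_indices(self, positions: np.ndarray) -> np.ndarray:
        """Vectorized (n,3) world positions -> (n,3) voxel indices.

        A position exactly on the upper domain face belongs to the last voxel.
        """
        p = (np.asarray(positions, dtype=float) - self.origin) / self.voxel_size
        shape = np.asarray(self.shape)
        if p.size and (p.min() < 0 or np.any(p > shape)):
            raise OutOfBoundsError("one or more positions outside grid bounds")
        idx = np.minimum(np.floor(p).astype(np.int64), shape - 1)
        return idx

    def flat_indices(self, positions: np.ndarray) -> np.ndarray:
        idx = self.voxel_indices(positions)
        return np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), self.shape)

    def concentration_at(self, position) -> float:
        """Concentration of the containing voxel (no interpolation)."""
        i, j, k = self.voxel_index(position)
        return float(self.conc[i, j, k])

    def concentrations_at(self, positions: np.ndarray) -> np.ndarray:
        idx = self.voxel_indices(positions)
        return self.conc[idx[:, 0], idx[:, 1], idx[:, 2]]

    def gradient_at(self, position) -> np.ndarray:
        """Central-difference gradient (µm⁻¹·conc) at the containing voxel.

        Boundary voxels fall back to one-sided differences.
        """
        idx = np.asarray(self.voxel_index(position))[None, :]
        return self._gradient(idx)[0]

    def gradients_at(self, positions: np.ndarray) -> np.ndarray:
        return self._gradient(self.voxel_indices(positions))

    def _gradient(self, idx: np.ndarray) -> np.ndarray:
        out = np.empty((idx.shape[0], 3), dtype=np.float64)
        shape = self.shape
        for ax in range(3):
            hi = np.minimum(idx[:, ax] + 1, shape[ax] - 1)
            lo = np.maximum(idx[:, ax] - 1, 0)
            span = (hi - lo) * self.voxel_size
            ih, il = idx.copy(), idx.copy()
            ih[:, ax] = hi
            il[:, ax] = lo
            num = (
                self.conc[ih[:, 0], ih[:, 1], ih[:, 2]]
                - self.conc[il[:, 0], il[:, 1], il[:, 2]]
            )
            with np.errstate(invalid="ignore"):
                out[:, ax] = np.where(span > 0, num / np.where(span > 0, span, 1.0), 0.0)
        return out

    # ------------------------------------------------------------------- misc
    def total_mass(self) -> float:
        return float(self.conc.sum())

    def check_nonnegative(self) -> None:
        m = self.conc.min()
        if m < 0:
            raise RuntimeError(
                f"negative concentration {m} in substance {self.substance_id}: "
                "scheme misuse (stability or external modification)"
            )

    def snapshot(self) -> dict:
        """JSON-serializable sidecar describing the grid (for exports)."""
        return {
            "substance_id": self.substance_id,
            "shape": list(self.shape),
            "voxel_size_um": self.voxel_size,
            "origin_um": self.origin.tolist(),
            "nu": self.nu,
            "mu": self.mu,
            "dt": self.dt,
            "substeps": self.substeps,
            "boundary": self.boundary,
        }


def steady_self_concentration(
    voxel_size: float = 2.0,
    slab_z: float = 22.0,
    nu: float = 2.0,
    mu: float = 0.0,
    substeps: int | None = None,
    boundary: str = "absorbing",
    steps: int = 300,
    lateral_extent: float = 160.0,
    dtype: str = "float64",
) -> float:
    """Steady own-voxel concentration of an isolated mid-plane point source.

    A single cell secreting one unit per step into an otherwise empty slab
    reaches a screened steady state within a few hundred steps (leakage
    through the slab faces balances secretion).  This level is the baseline
    every cell reads from its own secretion; death/migration thresholds only
    discriminate homotypic neighbours through their margin above it, so the
    calibration routines parameterize thresholds as ``self level + margin``.

    Deterministic; depends only on the discretization and boundary choice.
    """
    n_xy = max(9, int(np.ceil(lateral_extent / voxel_size)))
    n_z = max(3, int(np.ceil(slab_z / voxel_size)))
    grid = SubstanceGrid(
        substance_id="probe",
        shape=(n_xy, n_xy, n_z),
        voxel_size=voxel_size,
        nu=nu,
        mu=mu,
        substeps=substeps,
        boundary=boundary,
        dtype=dtype,
    )
    src = np.array([n_xy / 2.0 * voxel_size, n_xy / 2.0 * voxel_size, slab_z / 2.0])
    for _ in range(steps):
        grid.secrete(src, 1.0)
        grid.diffuse_step()
    return grid.concentration_at(src)


def lateral_kernel_profile(
    voxel_size: float = 2.0,
    slab_z: float = 22.0,
    nu: float = 2.0,
    mu: float = 0.0,
    substeps: int | None = None,
    boundary: str = "absorbing",
    steps: int = 400,
    lateral_extent: float = 400.0,
    dtype: str = "float64",
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state lateral concentration profile of an isolated source.

    Returns ``(radii_um, concentration)`` along the x axis from the source
    voxel outward.  In the thin absorbing slab the profile decays roughly
    exponentially with a screening length set by the slab thickness; it is
    the interaction kernel through which homotypic cells sense each other,
    and the basis for choosing locality-scale migration margins.
    """
    n_xy = max(9, int(np.ceil(lateral_extent / voxel_size)))
    n_z = max(3, int(np.ceil(slab_z / voxel_size)))
    grid = SubstanceGrid(
        substance_id="probe",
        shape=(n_xy, n_xy, n_z),
        voxel_size=voxel_size,
        nu=nu,
        mu=mu,
        substeps=substeps,
        boundary=boundary,
        dtype=dtype,
    )
    src = np.array([n_xy / 2.0 * voxel_size, n_xy / 2.0 * voxel_size, slab_z / 2.0])
    for _ in range(steps):
        grid.secrete(src, 1.0)
        grid.diffuse_step()
    i, j, k = grid.voxel_index(src)
    n_out = n_xy - i - 1
    radii = np.arange(n_out) * voxel_size
    profile = grid.conc[i : i + n_out, j, k].copy()
    return radii, profile


def kernel_value(radii: np.ndarray, profile: np.ndarray, r: np.ndarray | float) -> np.ndarray:
    """Log-linear interpolation of a kernel profile (clipped to its range)."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    positive = profile > 0
    logp = np.log(profile[positive])
    out = np.interp(r, radii[positive], logp)
    return np.exp(out)


def export_grid(grid: SubstanceGrid, path) -> tuple:
    """Write a grid as a dense ``.npy`` array plus a JSON sidecar.

    The sidecar (``<path>.json``) records voxel size, origin, ν, μ, Δt and
    boundary so the array can be re-interpreted without the object.
    """
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, np.ascontiguousarray(grid.conc))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(grid.snapshot(), indent=2))
    return path, sidecar
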