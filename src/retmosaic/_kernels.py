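"""Numba kernels for the explicit central-difference diffusion update.

The update applied to every voxel is

    u'[i,j,k] = (u + a*(u[i+1]-2u+u[i-1]) + a*(u[j+1]-2u+u[j-1])
                   + a*(u[k+1]-2u+u[k-1])) * (1 - mu)

with a = nu*dt/dx**2 per sub-step.  Out-of-lattice neighbours are either
mirrored (reflecting / zero-flux boundary, conserves mass for mu=0) or taken
as zero (absorbing boundary, substance leaks out of the slab faces).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def diffuse_substep_padded(pad, out, alpha, mu):
    """7-point stencil over the interior of a ghost-padded lattice.

    ``pad`` and ``out`` are (nx+2, ny+2, nz+2); boundary ghosts of ``pad``
    already hold the mirrored (reflecting) or zero (absorbing) neighbour
    values.  Only the interior of ``out`` is written, so zero ghosts stay
    zero for the absorbing boundary.
    """
    nx, ny, nz = pad.shape[0] - 2, pad.shape[1] - 2, pad.shape[2] - 2
    keep = 1.0 - mu
    for i in range(1, nx + 1):
        for j in range(1, ny + 1):
            for k in range(1, nz + 1):
                c = pad[i, j, k]
                lap = (
                    pad[i + 1, j, k]
                    + pad[i - 1, j, k]
                    + pad[i, j + 1, k]
                    + pad[i, j - 1, k]
                    + pad[i, j, k + 1]
                    + pad[i, j, k - 1]
                    - 6.0 * c
                )
                out[i, j, k] = (c + alpha * lap) * keep


@njit(cache=True)
def resolve_overlaps(pos, radii, pairs_i, pairs_j, disp):
    """Accumulate symmetric half-overlap displacements for each touching pair.

    Returns the largest positive overlap seen (0 if none)."""
    max_overlap = 0.0
    for n in range(pairs_i.shape[0]):
        a = pairs_i[n]
        b = pairs_j[n]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        overlap = radii[a] + radii[b] - dist
        if overlap <= 0.0:
            continue
        if overlap > max_overlap:
            max_overlap = overlap
        if dist > 1e-12:
            f = 0.5 * overlap / dist
            ux, uy, uz = dx * f, dy * f, dz * f
        else:
            # coincident centres: deterministic symmetry-breaking along x
            ux, uy, uz = 0.5 * overlap, 0.0, 0.0
        disp[a, 0] += ux
        disp[a, 1] += uy
        disp[a, 2] += uz
        disp[b, 0] -= ux
        disp[b, 1] -= uy
        disp[b, 2] -= uz
    return max_overlap
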