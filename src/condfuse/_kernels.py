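"""Compiled inner loops for the force evaluation.

Numba is used when importable (it is an optional dependency); otherwise
``HAVE_NUMBA`` is False and the engine falls back to the vectorized
numpy implementation in :mod:`condfuse.dynamics`, which computes exactly
the same quantities.  Kernels accumulate forces in place and return the
potential-energy contribution.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def lj_forces(pos, pairs, skip, partner, box, sigma2, ens, rmax2, e_shift, F):
    """Truncated LJ over the neighbor-pair list.

    ``skip`` marks intrachain exclusions; pairs that are currently bonded
    stickers are suppressed via ``partner``.  ``e_shift`` is the energy
    subtracted inside the cutoff when truncation is shifted (0 for plain).
    """
    energy = 0.0
    for k in range(pairs.shape[0]):
        if skip[k]:
            continue
        i = pairs[k, 0]
        j = pairs[k, 1]
        if partner[i] == j:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rmax2:
            continue
        sr6 = (sigma2 / r2) ** 3
        energy += 4.0 * ens * (sr6 * sr6 - sr6) - e_shift
        f_over_r = 4.0 * ens * (12.0 * sr6 * sr6 - 6.0 * sr6) / r2
        F[i, 0] += f_over_r * dx
        F[i, 1] += f_over_r * dy
        F[i, 2] += f_over_r * dz
        F[j, 0] -= f_over_r * dx
        F[j, 1] -= f_over_r * dy
        F[j, 2] -= f_over_r * dz
    return energy


@njit(cache=False)
def max_disp_exceeds(pos, ref, thresh_sq):
    """True as soon as any bead has moved further than sqrt(thresh_sq)
    from its reference position (raw displacement, no minimum image —
    a periodic jump only forces a harmless extra rebuild)."""
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        if dx * dx + dy * dy + dz * dz > thresh_sq:
            return True
    return False


@njit(cache=False)
def backbone_forces(pos, bonds, box, kb, r0, F):
    """Harmonic springs Kb (R - R0)^2 over the backbone bond list."""
    energy = 0.0
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        energy += kb * dr * dr
        fmag = -2.0 * kb * dr / r
        F[i, 0] += fmag * dx
        F[i, 1] += fmag * dy
        F[i, 2] += fmag * dz
        F[j, 0] -= fmag * dx
        F[j, 1] -= fmag * dy
        F[j, 2] -= fmag * dz
    return energy


@njit(cache=False)
def bending_forces(pos, triplets, box, kappa, F):
    """kappa (1 - cos theta) over (a, b, c) backbone triplets, theta the
    deflection between bond vectors b-a and c-b."""
    energy = 0.0
    for k in range(triplets.shape[0]):
        a = triplets[k, 0]
        b = triplets[k, 1]
        c = triplets[k, 2]
        b1x = pos[b, 0] - pos[a, 0]
        b1y = pos[b, 1] - pos[a, 1]
        b1z = pos[b, 2] - pos[a, 2]
        b2x = pos[c, 0] - pos[b, 0]
        b2y = pos[c, 1] - pos[b, 1]
        b2z = pos[c, 2] - pos[b, 2]
        b1x -= box * np.round(b1x / box)
        b1y -= box * np.round(b1y / box)
        b1z -= box * np.round(b1z / box)
        b2x -= box * np.round(b2x / box)
        b2y -= box * np.round(b2y / box)
        b2z -= box * np.round(b2z / box)
        n1sq = b1x * b1x + b1y * b1y + b1z * b1z
        n2sq = b2x * b2x + b2y * b2y + b2z * b2z
        n1 = np.sqrt(n1sq)
        n2 = np.sqrt(n2sq)
        dot = b1x * b2x + b1y * b2y + b1z * b2z
        cos = dot / (n1 * n2)
        if cos > 1.0:
            cos = 1.0
        elif cos < -1.0:
            cos = -1.0
        energy += kappa * (1.0 - cos)
        inv12 = 1.0 / (n1 * n2)
        c1 = cos / n1sq
        c2 = cos / n2sq
        # dcos/db1 and dcos/db2
        g1x = b2x * inv12 - b1x * c1
        g1y = b2y * inv12 - b1y * c1
        g1z = b2z * inv12 - b1z * c1
        g2x = b1x * inv12 - b2x * c2
        g2y = b1y * inv12 - b2y * c2
        g2z = b1z * inv12 - b2z * c2
        fax = -kappa * g1x
        fay = -kappa * g1y
        faz = -kappa * g1z
        fcx = kappa * g2x
        fcy = kappa * g2y
        fcz = kappa * g2z
        F[a, 0] += fax
        F[a, 1] += fay
        F[a, 2] += faz
        F[c, 0] += fcx
        F[c, 1] += fcy
        F[c, 2] += fcz
        F[b, 0] -= fax + fcx
        F[b, 1] -= fay + fcy
        F[b, 2] -= faz + fcz
    return energy


@njit(cache=False)
def bond_forces(pos, pairs, box, a_coef, r0, rcut, F):
    """Shifted-harmonic sticker bonds over the bonded-pair list."""
    energy = 0.0
    w2 = (rcut - r0) * (rcut - r0)
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= rcut:
            continue
        dr = r - r0
        energy += a_coef * (dr * dr - w2)
        fmag = -2.0 * a_coef * dr / r
        F[i, 0] += fmag * dx
        F[i, 1] += fmag * dy
        F[i, 2] += fmag * dz
        F[j, 0] -= fmag * dx
        F[j, 1] -= fmag * dy
        F[j, 2] -= fmag * dz
    return energy
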