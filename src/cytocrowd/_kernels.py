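"""Numba kernels: pair forces (brute-force and linked-cell) and BD propagation.

Units follow the package convention (A, ps, kBT).  Forces are in kBT/A so a
Brownian displacement is D*F*dt with D in A^2/ps.

Potential forms (``pot`` flag):
  0  half-harmonic excluded-volume repulsion,
       V = k/2 (r - ai - aj - delta)^2 for r < ai + aj + delta, else 0
  1  Lennard-Jones with Rmin_ij = ai + aj (minimum at sphere contact)
  2  Lennard-Jones + truncated Coulomb (Bjerrum-length prefactor ``lb``)
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = -1  # propagation status: -1 ok, >= 0 index of unstable particle

_SIX_ROOT_TWO = 2.0 ** (1.0 / 6.0)


@njit(cache=False)
def _pair_ef(r, ai, aj, qi, qj, pot, k, delta, eps, lb, rcut):
    """Energy and force magnitude (dV/dr with sign flipped) for one pair."""
    e = 0.0
    f = 0.0
    if pot == 0:
        cut = ai + aj + delta
        if r < cut:
            x = r - cut
            e = 0.5 * k * x * x
            f = -k * x
    else:
        if r < rcut:
            sigma = (ai + aj) / _SIX_ROOT_TWO
            sr6 = (sigma / r) ** 6
            e = 4.0 * eps * (sr6 * sr6 - sr6)
            f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
            if pot == 2 and qi != 0.0 and qj != 0.0:
                e += lb * qi * qj / r
                f += lb * qi * qj / (r * r)
    return e, f


@njit(cache=False)
def forces_brute(pos, radii, charges, L, pot, k, delta, eps, lb, rcut, out):
    """All-pairs minimum-image forces; returns total potential energy."""
    n = pos.shape[0]
    for i in range(n):
        out[i, 0] = 0.0
        out[i, 1] = 0.0
        out[i, 2] = 0.0
    etot = 0.0
    rcut2 = rcut * rcut
    if pot == 0:
        # half-harmonic: per-pair squared-distance rejection before any sqrt
        for i in range(n - 1):
            xi = pos[i, 0]
            yi = pos[i, 1]
            zi = pos[i, 2]
            ai = radii[i]
            for j in range(i + 1, n):
                dx = xi - pos[j, 0]
                dy = yi - pos[j, 1]
                dz = zi - pos[j, 2]
                dx -= L * np.rint(dx / L)
                dy -= L * np.rint(dy / L)
                dz -= L * np.rint(dz / L)
                r2 = dx * dx + dy * dy + dz * dz
                cut = ai + radii[j] + delta
                if r2 < cut * cut:
                    if r2 < 1e-20:
                        return np.nan  # singular configuration
                    r = np.sqrt(r2)
                    x = r - cut
                    etot += 0.5 * k * x * x
                    f = -k * x / r
                    out[i, 0] += f * dx
                    out[i, 1] += f * dy
                    out[i, 2] += f * dz
                    out[j, 0] -= f * dx
                    out[j, 1] -= f * dy
                    out[j, 2] -= f * dz
    else:
        for i in range(n - 1):
            xi = pos[i, 0]
            yi = pos[i, 1]
            zi = pos[i, 2]
            ai = radii[i]
            for j in range(i + 1, n):
                dx = xi - pos[j, 0]
                dy = yi - pos[j, 1]
                dz = zi - pos[j, 2]
                dx -= L * np.rint(dx / L)
                dy -= L * np.rint(dy / L)
                dz -= L * np.rint(dz / L)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rcut2:
                    if r2 < 1e-20:
                        return np.nan
                    sigma = (ai + radii[j]) / _SIX_ROOT_TWO
                    sr2 = sigma * sigma / r2
                    sr6 = sr2 * sr2 * sr2
                    etot += 4.0 * eps * (sr6 * sr6 - sr6)
                    # f/r so force components avoid an extra sqrt
                    f_over_r = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
                    if pot == 2 and charges[i] != 0.0 and charges[j] != 0.0:
                        r = np.sqrt(r2)
                        etot += lb * charges[i] * charges[j] / r
                        f_over_r += lb * charges[i] * charges[j] / (r2 * r)
                    out[i, 0] += f_over_r * dx
                    out[i, 1] += f_over_r * dy
                    out[i, 2] += f_over_r * dz
                    out[j, 0] -= f_over_r * dx
                    out[j, 1] -= f_over_r * dy
                    out[j, 2] -= f_over_r * dz
    return etot


@njit(cache=False)
def forces_cells(pos, radii, charges, L, pot, k, delta, eps, lb, rcut,
                 ncell, out):
    """Linked-cell forces; exact for cell size >= interaction range, ncell >= 4."""
    n = pos.shape[0]
    for i in range(n):
        out[i, 0] = 0.0
        out[i, 1] = 0.0
        out[i, 2] = 0.0
    cs = L / ncell
    ncell3 = ncell * ncell * ncell
    head = np.full(ncell3, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cellof = np.empty(n, dtype=np.int64)
    for i in range(n):
        # floor (not truncation) so negative unwrapped coordinates map to
        # the correct periodic cell
        ix = int(np.floor(pos[i, 0] / cs)) % ncell
        iy = int(np.floor(pos[i, 1] / cs)) % ncell
        iz = int(np.floor(pos[i, 2] / cs)) % ncell
        if ix < 0:
            ix += ncell
        if iy < 0:
            iy += ncell
        if iz < 0:
            iz += ncell
        c = (ix * ncell + iy) * ncell + iz
        cellof[i] = c
        nxt[i] = head[c]
        head[c] = i
    # 13 half-stencil neighbour offsets + self
    offs = np.array([
        [0, 0, 0],
        [1, 0, 0], [0, 1, 0], [0, 0, 1],
        [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1],
        [0, 1, 1], [0, 1, -1],
        [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
    ], dtype=np.int64)
    etot = 0.0
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c1 = (cx * ncell + cy) * ncell + cz
                for o in range(offs.shape[0]):
                    nx = (cx + offs[o, 0]) % ncell
                    ny = (cy + offs[o, 1]) % ncell
                    nz = (cz + offs[o, 2]) % ncell
                    c2 = (nx * ncell + ny) * ncell + nz
                    i = head[c1]
                    while i >= 0:
                        if o == 0:
                            j = nxt[i]
                        else:
                            j = head[c2]
                        while j >= 0:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= L * np.rint(dx / L)
                            dy -= L * np.rint(dy / L)
                            dz -= L * np.rint(dz / L)
                            r2 = dx * dx + dy * dy + dz * dz
                            skip = False
                            if pot == 0:
                                cut = radii[i] + radii[j] + delta
                                if r2 >= cut * cut:
                                    skip = True
                            elif r2 >= rcut * rcut:
                                skip = True
                            if not skip:
                                if r2 < 1e-20:
                                    return np.nan
                                r = np.sqrt(r2)
                                e, f = _pair_ef(r, radii[i], radii[j],
                                                charges[i], charges[j],
                                                pot, k, delta, eps, lb, rcut)
                                etot += e
                                fx = f * dx / r
                                fy = f * dy / r
                                fz = f * dz / r
                                out[i, 0] += fx
                                out[i, 1] += fy
                                out[i, 2] += fz
                                out[j, 0] -= fx
                                out[j, 1] -= fy
                                out[j, 2] -= fz
                            j = nxt[j]
                        i = nxt[i]
    return etot


@njit(cache=False)
def _cap_forces(F, fcap):
    if fcap > 0.0:
        n = F.shape[0]
        for i in range(n):
            m = np.sqrt(F[i, 0] ** 2 + F[i, 1] ** 2 + F[i, 2] ** 2)
            if m > fcap:
                s = fcap / m
                F[i, 0] *= s
                F[i, 1] *= s
                F[i, 2] *= s


@njit(cache=False)
def propagate(pos, radii, charges, dpart, L, dt, pot, k, delta, eps, lb, rcut,
              scheme, ncell, noise, fcap, max_disp,
              step0, stride, frames, frame_times, energies, nframes0):
    """Advance ``noise.shape[0]`` BD steps in place.

    pos holds unwrapped coordinates; forces use minimum image.  ``scheme``
    0 = first-order (Ermak-McCammon), 1 = predictor-corrector
    (Iniesta-de la Torre) reusing the same noise realisation in both
    half-updates.  Frames are stored whenever the global step counter hits
    ``stride``.  Returns (status, nframes) where status is STATUS_OK or the
    index of a particle that moved more than ``max_disp`` in one step.
    """
    nsteps = noise.shape[0]
    n = pos.shape[0]
    F = np.empty((n, 3))
    F2 = np.empty((n, 3))
    posp = np.empty((n, 3))
    nframes = nframes0
    for s in range(nsteps):
        if ncell >= 4:
            e = forces_cells(pos, radii, charges, L, pot, k, delta, eps, lb,
                             rcut, ncell, F)
        else:
            e = forces_brute(pos, radii, charges, L, pot, k, delta, eps, lb,
                             rcut, F)
        if np.isnan(e):
            return -2, nframes
        _cap_forces(F, fcap)
        if scheme == 0:
            for i in range(n):
                amp = np.sqrt(2.0 * dpart[i] * dt)
                for d in range(3):
                    step = dpart[i] * F[i, d] * dt + amp * noise[s, i, d]
                    if np.abs(step) > max_disp:
                        return i, nframes
                    pos[i, d] += step
        else:
            for i in range(n):
                amp = np.sqrt(2.0 * dpart[i] * dt)
                for d in range(3):
                    posp[i, d] = pos[i, d] + dpart[i] * F[i, d] * dt \
                        + amp * noise[s, i, d]
            if ncell >= 4:
                e2 = forces_cells(posp, radii, charges, L, pot, k, delta, eps,
                                  lb, rcut, ncell, F2)
            else:
                e2 = forces_brute(posp, radii, charges, L, pot, k, delta, eps,
                                  lb, rcut, F2)
            if np.isnan(e2):
                return -2, nframes
            _cap_forces(F2, fcap)
            for i in range(n):
                amp = np.sqrt(2.0 * dpart[i] * dt)
                for d in range(3):
                    step = 0.5 * dpart[i] * (F[i, d] + F2[i, d]) * dt \
                        + amp * noise[s, i, d]
                    if np.abs(step) > max_disp:
                        return i, nframes
                    pos[i, d] += step
        gstep = step0 + s + 1
        if gstep % stride == 0:
            for i in range(n):
                frames[nframes, i, 0] = pos[i, 0]
                frames[nframes, i, 1] = pos[i, 1]
                frames[nframes, i, 2] = pos[i, 2]
            frame_times[nframes] = gstep * dt
            energies[nframes] = e
            nframes += 1
    return STATUS_OK, nframes


@njit(cache=False)
def count_within(pos_a, pos_b, L, cutoff):
    """Number of points in pos_b within minimum-image cutoff of each pos_a row."""
    na = pos_a.shape[0]
    nb = pos_b.shape[0]
    out = np.zeros(na, dtype=np.int64)
    c2 = cutoff * cutoff
    for i in range(na):
        for j in range(nb):
            dx = pos_a[i, 0] - pos_b[j, 0]
            dy = pos_a[i, 1] - pos_b[j, 1]
            dz = pos_a[i, 2] - pos_b[j, 2]
            dx -= L * np.rint(dx / L)
            dy -= L * np.rint(dy / L)
            dz -= L * np.rint(dz / L)
            if dx * dx + dy * dy + dz * dz <= c2:
                out[i] += 1
    return out
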