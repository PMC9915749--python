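"""Compiled force kernels (numba).

These implement exactly the same math as the reference functions in
:mod:`fibrilsim.forcefield`; the unit tests cross-check the two routes
against each other and against finite differences of the energy.

Sign conventions: for a bond/pair (i, j) with d = x[j] - x[i], u = d/r, a
positive bond tension T adds +T*u to the force on i (pulls i toward j).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def bond_kernel(x, bonds, r0, r1, rb, k0, k1, a, printed, rmax, update_state, f, tension):
    """Accumulate bond forces into f, write per-bond tension, return E_bond.

    Per-bond parameter arrays are pre-expanded (one entry per bond).  ``rmax``
    is the running maximum separation per bond; it is advanced in place only
    when ``update_state`` is true, so that energy evaluations (minimization,
    finite-difference checks) remain pure functions of the coordinates.
    """
    nb = bonds.shape[0]
    e_total = 0.0
    for b in range(nb):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if update_state and r > rmax[b]:
            rmax[b] = r
        dead_at = rb[b] + a[b]
        d1 = r1[b] - r0[b]
        if not printed:
            fb = k0[b] * d1 + k1[b] * (rb[b] - r1[b])
            e_r1 = 0.5 * k0[b] * d1 * d1
            e_rb = e_r1 + k0[b] * d1 * (rb[b] - r1[b]) + 0.5 * k1[b] * (rb[b] - r1[b]) ** 2
            e_plat = e_rb + 0.5 * fb * a[b]
            if rmax[b] >= dead_at:
                t = 0.0
                e = e_plat
            elif r < r1[b]:
                t = k0[b] * (r - r0[b])
                e = 0.5 * k0[b] * (r - r0[b]) ** 2
            elif r < rb[b]:
                t = k0[b] * d1 + k1[b] * (r - r1[b])
                e = e_r1 + k0[b] * d1 * (r - r1[b]) + 0.5 * k1[b] * (r - r1[b]) ** 2
            elif r < dead_at:
                s = r - rb[b]
                t = fb * (1.0 - s / a[b])
                e = e_rb + fb * s - fb * s * s / (2.0 * a[b])
            else:
                t = 0.0
                e = e_plat
        else:
            z = a[b] / (rb[b] - r1[b])
            e_r1 = 0.5 * k0[b] * d1 * d1
            e_rb = e_r1 + 0.5 * k1[b] * ((rb[b] - r0[b]) ** 2 - d1 * d1)
            e_plat = e_rb - 0.5 * z * k1[b] * ((dead_at - r0[b]) ** 2 - (rb[b] - r0[b]) ** 2)
            if rmax[b] >= dead_at:
                t = 0.0
                e = e_plat
            elif r < r1[b]:
                t = k0[b] * (r - r0[b])
                e = 0.5 * k0[b] * (r - r0[b]) ** 2
            elif r < rb[b]:
                t = k1[b] * (r - r0[b])
                e = e_r1 + 0.5 * k1[b] * ((r - r0[b]) ** 2 - d1 * d1)
            elif r < dead_at:
                t = -z * k1[b] * (r - r0[b])
                e = e_rb - 0.5 * z * k1[b] * ((r - r0[b]) ** 2 - (rb[b] - r0[b]) ** 2)
            else:
                t = 0.0
                e = e_plat
        tension[b] = t
        e_total += e
        if r > 1e-12:
            s = t / r
            f[i, 0] += s * dx
            f[i, 1] += s * dy
            f[i, 2] += s * dz
            f[j, 0] -= s * dx
            f[j, 1] -= s * dy
            f[j, 2] -= s * dz
    return e_total


@njit(cache=True)
def angle_kernel(x, angles, kb, phi0, f):
    """Harmonic angle bending; phi0 in radians; returns E_angle."""
    na = angles.shape[0]
    e_total = 0.0
    for t in range(na):
        i = angles[t, 0]
        j = angles[t, 1]  # apex
        k = angles[t, 2]
        ax = x[i, 0] - x[j, 0]
        ay = x[i, 1] - x[j, 1]
        az = x[i, 2] - x[j, 2]
        bx = x[k, 0] - x[j, 0]
        by = x[k, 1] - x[j, 1]
        bz = x[k, 2] - x[j, 2]
        la = np.sqrt(ax * ax + ay * ay + az * az)
        lb = np.sqrt(bx * bx + by * by + bz * bz)
        if la < 1e-12 or lb < 1e-12:
            continue
        ux, uy, uz = ax / la, ay / la, az / la
        vx, vy, vz = bx / lb, by / lb, bz / lb
        c = ux * vx + uy * vy + uz * vz
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        phi = np.arccos(c)
        dphi = phi - phi0[t]
        e_total += 0.5 * kb[t] * dphi * dphi
        s = np.sqrt(1.0 - c * c)
        if s < 1e-12:
            s = 1e-12
        # F_i = kb*dphi/(la*s) * (v - c*u);  F_k symmetric;  F_j = -F_i - F_k
        pref_i = kb[t] * dphi / (la * s)
        pref_k = kb[t] * dphi / (lb * s)
        fix = pref_i * (vx - c * ux)
        fiy = pref_i * (vy - c * uy)
        fiz = pref_i * (vz - c * uz)
        fkx = pref_k * (ux - c * vx)
        fky = pref_k * (uy - c * vy)
        fkz = pref_k * (uz - c * vz)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz
    return e_total


@njit(cache=True)
def pair_kernel(x, pi, pj, eps, sig, lam, rc, f):
    """Soft-core LJ over a candidate pair list; returns E_inter.

    Energy is shifted to zero at the cutoff rc; pairs beyond rc contribute
    nothing (the candidate list may include them because of the Verlet skin).
    """
    n = pi.shape[0]
    rsc = lam * sig
    sr6c = (sig / rsc) ** 6
    f_core = (48.0 * eps * sr6c * sr6c - 24.0 * eps * sr6c) / rsc
    e_core0 = 4.0 * eps * (sr6c * sr6c - sr6c)
    sr6cut = (sig / rc) ** 6
    e_shift = 4.0 * eps * (sr6cut * sr6cut - sr6cut)
    e_total = 0.0
    for p in range(n):
        i = pi[p]
        j = pj[p]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc * rc:
            continue
        r = np.sqrt(r2)
        if r < rsc:
            fr = f_core
            e = e_core0 + f_core * (rsc - r) - e_shift
        else:
            sr6 = (sig / r) ** 6
            fr = (48.0 * eps * sr6 * sr6 - 24.0 * eps * sr6) / r
            e = 4.0 * eps * (sr6 * sr6 - sr6) - e_shift
        e_total += e
        # fr = -dU/dr; force on i is -(fr)*u with u = d/r
        s = -fr / max(r, 1e-12)
        f[i, 0] += s * dx
        f[i, 1] += s * dy
        f[i, 2] += s * dz
        f[j, 0] -= s * dx
        f[j, 1] -= s * dy
        f[j, 2] -= s * dz
    return e_total
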