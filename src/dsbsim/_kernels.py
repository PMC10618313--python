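"""Numba kernels: force evaluation, Langevin integration, grid flood fill.

Everything in this module works on plain contiguous float64/int64 arrays in
internal units (Å, ε, τ, m=1).  The public modules pack their data into the
argument layout expected here; nothing outside this file should need numba.

Periodic convention: the in-plane cell is ``[[ax, bx], [0, by]]`` (X vector
along x, Y vector tilted by the shear ``bx``); Z is bounded by walls and is
never wrapped.  The in-kernel minimum image uses fractional rounding, which
is exact as long as interaction cutoffs stay below half the cell extents and
the tilt is moderate (|bx| < ax/2) - both guaranteed by the protocol driver.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

# energy-breakdown slot indices
E_BOND, E_ANGLE, E_DIHEDRAL, E_EXCLUDED = 0, 1, 2, 3
E_BB, E_BS, E_SS, E_GO, E_DISULFIDE, E_ELEC, E_WALL = 4, 5, 6, 7, 8, 9, 10
N_ETERMS = 11

# contact kind codes
K_BB, K_BS, K_SB, K_SS, K_DISULFIDE, K_GO = 0, 1, 2, 3, 4, 5

_E_SLOT_OF_KIND = np.array([E_BB, E_BS, E_BS, E_SS, E_DISULFIDE, E_GO],
                           dtype=np.int64)

# Soft-core linearization radii: below these separations the steep r^-12 /
# z^-9 cores continue linearly (C^1), keeping forces bounded.  The walls
# of energy there (thousands of ε) are thermally unreachable, so dynamics
# are unaffected; only numerical blow-ups from pathological overlaps are.
RMIN_PAIR = 2.5   # Å, excluded volume and contact wells
RMIN_WALL = 2.0   # Å, wall potentials


@njit(cache=False)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False, inline="always")
def _mi(dx, dy, ax, bx, by):
    """Minimum-image wrap of an in-plane displacement (fractional rounding)."""
    ny = math.floor(dy / by + 0.5)
    dy -= ny * by
    dx -= ny * bx
    dx -= math.floor(dx / ax + 0.5) * ax
    return dx, dy


@njit(cache=False)
def build_pairs(pos, cell, cutoff, chain_id):
    """All-pairs neighbor list within ``cutoff`` (min image), i<j.

    Skips chain-bonded neighbors (same chain, j=i+1).  Returns (M,2) indices
    and an (M,) flag: 0 for next-nearest chain neighbors (j=i+2, excluded
    volume only), 1 otherwise.
    """
    n = pos.shape[0]
    ax, bx, by = cell[0], cell[1], cell[2]
    c2 = cutoff * cutoff
    # first pass: count
    cnt = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j - i == 1:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx, dy = _mi(dx, dy, ax, bx, by)
            if dx * dx + dy * dy + dz * dz < c2:
                cnt += 1
    pairs = np.empty((cnt, 2), dtype=np.int64)
    flag = np.empty(cnt, dtype=np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j - i == 1:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx, dy = _mi(dx, dy, ax, bx, by)
            if dx * dx + dy * dy + dz * dz < c2:
                pairs[k, 0] = i
                pairs[k, 1] = j
                if chain_id[i] == chain_id[j] and j - i == 2:
                    flag[k] = 0
                else:
                    flag[k] = 1
                k += 1
    return pairs, flag


@njit(cache=False, inline="always")
def _spline_eval(x, x0, h, coef):
    """Evaluate a piecewise-cubic spline (scipy layout c[4, m]) and slope."""
    m = coef.shape[1]
    idx = int(math.floor((x - x0) / h))
    if idx < 0:
        idx = 0
    elif idx > m - 1:
        idx = m - 1
    t = x - (x0 + idx * h)
    c0 = coef[0, idx]
    c1 = coef[1, idx]
    c2 = coef[2, idx]
    c3 = coef[3, idx]
    v = ((c0 * t + c1) * t + c2) * t + c3
    dv = (3.0 * c0 * t + 2.0 * c1) * t + c2
    return v, dv


@njit(cache=False, fastmath=True)
def compute_forces(pos, cell,
                   bonds, k_bond, r_bond,
                   angles, ang_c, ang_x0, ang_h,
                   diheds, dih_c, dih_x0, dih_h,
                   pairs, pair_flag, pair_cidx,
                   con_r0, con_depth, con_lam, con_kind,
                   q, q_pref, debye_len, elec_cut,
                   r_excl,
                   wall_on, wall_sigma, wall_r0, wall_depth, wall_cut,
                   wall_lam_lo, wall_lam_hi,
                   frc, ebrk):
    """Full force-field evaluation.  Fills ``frc`` (N,3) and ``ebrk`` (11,)."""
    n = pos.shape[0]
    ax, bx, by = cell[0], cell[1], cell[2]
    z_lo, z_hi = cell[3], cell[4]
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0
    for t in range(N_ETERMS):
        ebrk[t] = 0.0

    # --- harmonic bonds: V = k (r - r_b)^2 ------------------------------
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy = _mi(dx, dy, ax, bx, by)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        dr = r - r_bond
        ebrk[E_BOND] += k_bond * dr * dr
        fpr = -2.0 * k_bond * dr / r
        frc[i, 0] += fpr * dx
        frc[i, 1] += fpr * dy
        frc[i, 2] += fpr * dz
        frc[j, 0] -= fpr * dx
        frc[j, 1] -= fpr * dy
        frc[j, 2] -= fpr * dz

    # --- tabulated bond angles ------------------------------------------
    for a in range(angles.shape[0]):
        ia = angles[a, 0]
        ib = angles[a, 1]
        ic = angles[a, 2]
        ux = pos[ia, 0] - pos[ib, 0]
        uy = pos[ia, 1] - pos[ib, 1]
        uz = pos[ia, 2] - pos[ib, 2]
        ux, uy = _mi(ux, uy, ax, bx, by)
        vx = pos[ic, 0] - pos[ib, 0]
        vy = pos[ic, 1] - pos[ib, 1]
        vz = pos[ic, 2] - pos[ib, 2]
        vx, vy = _mi(vx, vy, ax, bx, by)
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-12 or nv < 1e-12:
            continue
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        st = math.sqrt(1.0 - ct * ct)
        if st < 1e-8:
            continue  # collinear: frame degenerate, no angle force this step
        theta = math.acos(ct)
        v, dv = _spline_eval(theta, ang_x0, ang_h, ang_c)
        ebrk[E_ANGLE] += v
        # dtheta/da = (ct*uhat - vhat) / (|u| st); similarly for c
        coef_a = 1.0 / (nu * st)
        gax = (ct * ux / nu - vx / nv) * coef_a
        gay = (ct * uy / nu - vy / nv) * coef_a
        gaz = (ct * uz / nu - vz / nv) * coef_a
        coef_c = 1.0 / (nv * st)
        gcx = (ct * vx / nv - ux / nu) * coef_c
        gcy = (ct * vy / nv - uy / nu) * coef_c
        gcz = (ct * vz / nv - uz / nu) * coef_c
        frc[ia, 0] -= dv * gax
        frc[ia, 1] -= dv * gay
        frc[ia, 2] -= dv * gaz
        frc[ic, 0] -= dv * gcx
        frc[ic, 1] -= dv * gcy
        frc[ic, 2] -= dv * gcz
        frc[ib, 0] += dv * (gax + gcx)
        frc[ib, 1] += dv * (gay + gcy)
        frc[ib, 2] += dv * (gaz + gcz)

    # --- tabulated dihedrals --------------------------------------------
    for d in range(diheds.shape[0]):
        i1 = diheds[d, 0]
        i2 = diheds[d, 1]
        i3 = diheds[d, 2]
        i4 = diheds[d, 3]
        b1x = pos[i2, 0] - pos[i1, 0]
        b1y = pos[i2, 1] - pos[i1, 1]
        b1z = pos[i2, 2] - pos[i1, 2]
        b1x, b1y = _mi(b1x, b1y, ax, bx, by)
        b2x = pos[i3, 0] - pos[i2, 0]
        b2y = pos[i3, 1] - pos[i2, 1]
        b2z = pos[i3, 2] - pos[i2, 2]
        b2x, b2y = _mi(b2x, b2y, ax, bx, by)
        b3x = pos[i4, 0] - pos[i3, 0]
        b3y = pos[i4, 1] - pos[i3, 1]
        b3z = pos[i4, 2] - pos[i3, 2]
        b3x, b3y = _mi(b3x, b3y, ax, bx, by)
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-16 or n2sq < 1e-16 or nb2 < 1e-12:
            continue
        # phi = atan2((n1 x n2).b2hat, n1.n2)
        mx = n1y * n2z - n1z * n2y
        my = n1z * n2x - n1x * n2z
        mz = n1x * n2y - n1y * n2x
        sy = (mx * b2x + my * b2y + mz * b2z) / nb2
        sx = n1x * n2x + n1y * n2y + n1z * n2z
        phi = math.atan2(sy, sx)
        v, dv = _spline_eval(phi, dih_x0, dih_h, dih_c)
        ebrk[E_DIHEDRAL] += v
        # dphi/dr1 = -|b2|/|n1|^2 n1 ; dphi/dr4 = |b2|/|n2|^2 n2
        ca = -nb2 / n1sq
        g1x = ca * n1x
        g1y = ca * n1y
        g1z = ca * n1z
        cb = nb2 / n2sq
        g4x = cb * n2x
        g4y = cb * n2y
        g4z = cb * n2z
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        g2x = -(1.0 + s12) * g1x + s32 * g4x
        g2y = -(1.0 + s12) * g1y + s32 * g4y
        g2z = -(1.0 + s12) * g1z + s32 * g4z
        g3x = s12 * g1x - (1.0 + s32) * g4x
        g3y = s12 * g1y - (1.0 + s32) * g4y
        g3z = s12 * g1z - (1.0 + s32) * g4z
        frc[i1, 0] -= dv * g1x
        frc[i1, 1] -= dv * g1y
        frc[i1, 2] -= dv * g1z
        frc[i2, 0] -= dv * g2x
        frc[i2, 1] -= dv * g2y
        frc[i2, 2] -= dv * g2z
        frc[i3, 0] -= dv * g3x
        frc[i3, 1] -= dv * g3y
        frc[i3, 2] -= dv * g3z
        frc[i4, 0] -= dv * g4x
        frc[i4, 1] -= dv * g4y
        frc[i4, 2] -= dv * g4z

    # --- nonbonded pairs -------------------------------------------------
    do_elec = q_pref != 0.0
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy = _mi(dx, dy, ax, bx, by)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            # overlapping beads: signalled through a non-finite force
            frc[i, 0] = np.nan
            continue
        r = math.sqrt(r2)
        dvdr = 0.0
        cidx = pair_cidx[p]
        # excluded-volume part, weighted down while a contact is active
        w_ex = 1.0
        if cidx >= 0:
            w_ex = 1.0 - con_lam[cidx]
        if r < r_excl and w_ex > 0.0:
            re = r if r > RMIN_PAIR else RMIN_PAIR
            s2 = (r_excl / re) ** 2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            v = s12 - 2.0 * s6 + 1.0
            dv = (-12.0 / re) * (s12 - s6)
            if r < RMIN_PAIR:
                v += dv * (r - RMIN_PAIR)
            ebrk[E_EXCLUDED] += w_ex * v
            dvdr += w_ex * dv
        if pair_flag[p] == 1:
            if cidx >= 0:
                lam = con_lam[cidx]
                if lam > 0.0:
                    r0c = con_r0[cidx]
                    dep = con_depth[cidx]
                    re = r if r > RMIN_PAIR else RMIN_PAIR
                    s2c = (r0c / re) ** 2
                    s6c = s2c * s2c * s2c
                    s12c = s6c * s6c
                    v = dep * (s12c - 2.0 * s6c)
                    dv = dep * (-12.0 / re) * (s12c - s6c)
                    if r < RMIN_PAIR:
                        v += dv * (r - RMIN_PAIR)
                    ebrk[_E_SLOT_OF_KIND[con_kind[cidx]]] += lam * v
                    dvdr += lam * dv
            if do_elec and r < elec_cut:
                qq = q[i] * q[j]
                if qq != 0.0:
                    # screened Coulomb with eps_r(r) = kappa*r -> 1/r^2 law
                    ex = math.exp(-r / debye_len)
                    exc = math.exp(-elec_cut / debye_len)
                    e_el = q_pref * qq * (ex / r2 - exc / (elec_cut * elec_cut))
                    ebrk[E_ELEC] += e_el
                    dvdr += q_pref * qq * ex * (-2.0 / (r2 * r)
                                                - 1.0 / (debye_len * r2))
        fpr = -dvdr / r
        frc[i, 0] += fpr * dx
        frc[i, 1] += fpr * dy
        frc[i, 2] += fpr * dz
        frc[j, 0] -= fpr * dx
        frc[j, 1] -= fpr * dy
        frc[j, 2] -= fpr * dz

    # --- walls -----------------------------------------------------------
    if wall_on != 0:
        for i in range(n):
            for side in range(2):
                if side == 0:
                    dzw = pos[i, 2] - z_lo
                    lam = wall_lam_lo[i]
                    sgn = 1.0
                else:
                    dzw = z_hi - pos[i, 2]
                    lam = wall_lam_hi[i]
                    sgn = -1.0
                if dzw >= wall_cut:
                    continue
                de = dzw if dzw > RMIN_WALL else RMIN_WALL
                dvdd = 0.0
                if lam < 1.0:
                    s9 = (wall_sigma / de) ** 9
                    v = s9 / 9.0
                    dv = -s9 / de
                    if dzw < RMIN_WALL:
                        v += dv * (dzw - RMIN_WALL)
                    ebrk[E_WALL] += (1.0 - lam) * v
                    dvdd += (1.0 - lam) * dv
                if lam > 0.0:
                    s6w = (wall_r0 / de) ** 6
                    s12w = s6w * s6w
                    v = wall_depth * (s12w - 2.0 * s6w)
                    dv = wall_depth * (-12.0 / de) * (s12w - s6w)
                    if dzw < RMIN_WALL:
                        v += dv * (dzw - RMIN_WALL)
                    ebrk[E_WALL] += lam * v
                    dvdd += lam * dv
                frc[i, 2] += -dvdd * sgn
    total = 0.0
    for t in range(N_ETERMS):
        total += ebrk[t]
    return total


@njit(cache=False, fastmath=True)
def integrate_block(pos, vel, frc, nsteps, dt, gamma, mass, kBT,
                    noise, noise_on,
                    cell,
                    bonds, k_bond, r_bond,
                    angles, ang_c, ang_x0, ang_h,
                    diheds, dih_c, dih_x0, dih_h,
                    pairs, pair_flag, pair_cidx,
                    con_r0, con_depth, con_lam, con_kind,
                    q, q_pref, debye_len, elec_cut,
                    r_excl,
                    wall_on, wall_sigma, wall_r0, wall_depth, wall_cut,
                    wall_lam_lo, wall_lam_hi,
                    ebrk):
    """BAOAB Langevin steps; ``frc`` must hold forces for current ``pos``.

    ``noise`` holds pre-drawn standard normals, shape (nsteps, N, 3) when
    the thermostat is on.  Returns 0 on success, 1 on non-finite force.
    """
    n = pos.shape[0]
    c1 = math.exp(-gamma * dt / mass)
    if noise_on != 0:
        c2 = math.sqrt((1.0 - c1 * c1) * kBT / mass)
    else:
        c2 = 0.0
    half = 0.5 * dt
    for s in range(nsteps):
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * frc[i, k] / mass
                pos[i, k] += half * vel[i, k]
        if noise_on != 0:
            for i in range(n):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k] + c2 * noise[s, i, k]
        else:
            for i in range(n):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k]
        for i in range(n):
            for k in range(3):
                pos[i, k] += half * vel[i, k]
        compute_forces(pos, cell,
                       bonds, k_bond, r_bond,
                       angles, ang_c, ang_x0, ang_h,
                       diheds, dih_c, dih_x0, dih_h,
                       pairs, pair_flag, pair_cidx,
                       con_r0, con_depth, con_lam, con_kind,
                       q, q_pref, debye_len, elec_cut,
                       r_excl,
                       wall_on, wall_sigma, wall_r0, wall_depth, wall_cut,
                       wall_lam_lo, wall_lam_hi,
                       frc, ebrk)
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * frc[i, k] / mass
        if not math.isfinite(frc[0, 0]):
            return 1
    return 0


@njit(cache=False)
def integrate_free_block(vel, nsteps, dt, gamma, mass, kBT, noise_on):
    """Force-free BAOAB (thermostat only): accumulates sum of v^2 per step."""
    n = vel.shape[0]
    c1 = math.exp(-gamma * dt / mass)
    c2 = math.sqrt((1.0 - c1 * c1) * kBT / mass) if noise_on != 0 else 0.0
    acc = 0.0
    for s in range(nsteps):
        for i in range(n):
            for k in range(3):
                vel[i, k] = c1 * vel[i, k] + c2 * (
                    np.random.normal() if noise_on != 0 else 0.0)
        for i in range(n):
            for k in range(3):
                acc += vel[i, k] * vel[i, k]
    return acc


@njit(cache=False)
def max_displacement(pos, ref):
    n = pos.shape[0]
    best = 0.0
    for i in range(n):
        d = 0.0
        for k in range(3):
            t = pos[i, k] - ref[i, k]
            d += t * t
        if d > best:
            best = d
    return math.sqrt(best)


# ---------------------------------------------------------------------------
# grid flood fill (cavity detection)
# ---------------------------------------------------------------------------

@njit(cache=False)
def mark_occupied(centers, nx, ny, nz, hx, hy, hz, x0, y0, z0,
                  radius, periodic_xy, ax, by):
    """Occupancy grid: ball-center grid points within ``radius`` of any bead."""
    occ = np.zeros(nx * ny * nz, dtype=np.uint8)
    r2 = radius * radius
    mx = int(radius / hx) + 1
    my = int(radius / hy) + 1
    mz = int(radius / hz) + 1
    for c in range(centers.shape[0]):
        cx = centers[c, 0]
        cy = centers[c, 1]
        cz = centers[c, 2]
        ix = int(math.floor((cx - x0) / hx + 0.5))
        iy = int(math.floor((cy - y0) / hy + 0.5))
        iz = int(math.floor((cz - z0) / hz + 0.5))
        for di in range(-mx, mx + 1):
            gi = ix + di
            if periodic_xy != 0:
                gi = gi % nx
            elif gi < 0 or gi >= nx:
                continue
            for dj in range(-my, my + 1):
                gj = iy + dj
                if periodic_xy != 0:
                    gj = gj % ny
                elif gj < 0 or gj >= ny:
                    continue
                for dk in range(-mz, mz + 1):
                    gk = iz + dk
                    if gk < 0 or gk >= nz:
                        continue
                    px = x0 + (ix + di) * hx
                    py = y0 + (iy + dj) * hy
                    pz = z0 + gk * hz
                    ddx = px - cx
                    ddy = py - cy
                    ddz = pz - cz
                    if ddx * ddx + ddy * ddy + ddz * ddz <= r2:
                        occ[(gi * ny + gj) * nz + gk] = 1
    return occ


@njit(cache=False)
def flood_exterior(occ, nx, ny, nz, seeds, periodic_xy):
    """BFS from seed cells over empty cells (6-adjacency); marks exterior=2."""
    stack = np.empty(nx * ny * nz, dtype=np.int64)
    top = 0
    for s in range(seeds.shape[0]):
        idx = seeds[s]
        if occ[idx] == 0:
            occ[idx] = 2
            stack[top] = idx
            top += 1
    while top > 0:
        top -= 1
        idx = stack[top]
        iz = idx % nz
        iy = (idx // nz) % ny
        ix = idx // (nz * ny)
        for d in range(6):
            jx, jy, jz = ix, iy, iz
            if d == 0:
                jx += 1
            elif d == 1:
                jx -= 1
            elif d == 2:
                jy += 1
            elif d == 3:
                jy -= 1
            elif d == 4:
                jz += 1
            else:
                jz -= 1
            if jz < 0 or jz >= nz:
                continue
            if periodic_xy != 0:
                jx = jx % nx
                jy = jy % ny
            elif jx < 0 or jx >= nx or jy < 0 or jy >= ny:
                continue
            jdx = (jx * ny + jy) * nz + jz
            if occ[jdx] == 0:
                occ[jdx] = 2
                stack[top] = jdx
                top += 1
    return occ


@njit(cache=False)
def label_components(occ, nx, ny, nz, periodic_xy, conn26):
    """Label connected components of cells still 0 (cavity cells).

    Returns (labels array with -1 elsewhere, number of components).
    """
    labels = np.full(nx * ny * nz, -1, dtype=np.int64)
    stack = np.empty(nx * ny * nz, dtype=np.int64)
    ncomp = 0
    for start in range(nx * ny * nz):
        if occ[start] != 0 or labels[start] >= 0:
            continue
        labels[start] = ncomp
        top = 0
        stack[top] = start
        top += 1
        while top > 0:
            top -= 1
            idx = stack[top]
            iz = idx % nz
            iy = (idx // nz) % ny
            ix = idx // (nz * ny)
            for dx in range(-1, 2):
                for dy in range(-1, 2):
                    for dz in range(-1, 2):
                        if dx == 0 and dy == 0 and dz == 0:
                            continue
                        if conn26 == 0 and abs(dx) + abs(dy) + abs(dz) != 1:
                            continue
                        jx, jy, jz = ix + dx, iy + dy, iz + dz
                        if jz < 0 or jz >= nz:
                            continue
                        if periodic_xy != 0:
                            jx = jx % nx
                            jy = jy % ny
                        elif jx < 0 or jx >= nx or jy < 0 or jy >= ny:
                            continue
                        jdx = (jx * ny + jy) * nz + jz
                        if occ[jdx] == 0 and labels[jdx] < 0:
                            labels[jdx] = ncomp
                            stack[top] = jdx
                            top += 1
        ncomp += 1
    return labels, ncomp


# ---------------------------------------------------------------------------
# triangle/segment predicates (entanglement analysis)
# ---------------------------------------------------------------------------

@njit(cache=False, inline="always")
def _seg_tri(p0x, p0y, p0z, p1x, p1y, p1z,
             ax_, ay_, az_, bx_, by_, bz_, cx_, cy_, cz_):
    """Segment-triangle intersection (Moller-Trumbore), inclusive edges."""
    dx = p1x - p0x
    dy = p1y - p0y
    dz = p1z - p0z
    e1x = bx_ - ax_
    e1y = by_ - ay_
    e1z = bz_ - az_
    e2x = cx_ - ax_
    e2y = cy_ - ay_
    e2z = cz_ - az_
    hx = dy * e2z - dz * e2y
    hy = dz * e2x - dx * e2z
    hz = dx * e2y - dy * e2x
    det = e1x * hx + e1y * hy + e1z * hz
    if abs(det) < 1e-12:
        return False
    inv = 1.0 / det
    sx = p0x - ax_
    sy = p0y - ay_
    sz = p0z - az_
    u = (sx * hx + sy * hy + sz * hz) * inv
    if u < -1e-10 or u > 1.0 + 1e-10:
        return False
    qx = sy * e1z - sz * e1y
    qy = sz * e1x - sx * e1z
    qz = sx * e1y - sy * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-10 or u + v > 1.0 + 1e-10:
        return False
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t < -1e-10 or t > 1.0 + 1e-10:
        return False
    return True


@njit(cache=False)
def triangle_blocked(a, b, c, segs, seg_chain, skip_chain,
                     ax_cell, bx_cell, by_cell, periodic):
    """First chain whose segment crosses triangle (a,b,c); -1 if none.

    ``segs`` is (M, 6): endpoints of every segment of every chain; segments
    of ``skip_chain`` are ignored.  With ``periodic`` set, each segment is
    shifted by the in-plane lattice vector that brings its midpoint closest
    to the triangle centroid (minimum-image convention for slab cells).
    """
    gx = (a[0] + b[0] + c[0]) / 3.0
    gy = (a[1] + b[1] + c[1]) / 3.0
    for s in range(segs.shape[0]):
        if seg_chain[s] == skip_chain:
            continue
        p0x = segs[s, 0]
        p0y = segs[s, 1]
        p0z = segs[s, 2]
        p1x = segs[s, 3]
        p1y = segs[s, 4]
        p1z = segs[s, 5]
        if periodic != 0:
            mx = 0.5 * (p0x + p1x) - gx
            my = 0.5 * (p0y + p1y) - gy
            wx, wy = _mi(mx, my, ax_cell, bx_cell, by_cell)
            shx = wx - mx
            shy = wy - my
            p0x += shx
            p0y += shy
            p1x += shx
            p1y += shy
        if _seg_tri(p0x, p0y, p0z, p1x, p1y, p1z,
                    a[0], a[1], a[2], b[0], b[1], b[2], c[0], c[1], c[2]):
            return seg_chain[s]
    return -1
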