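"""Numba kernels: pair forces, cell lists and the Langevin integrator.

These are private; the public surfaces live in :mod:`twitchsim.forces`
and :mod:`twitchsim.engine`.  All kernels use the minimum-image
convention in a square periodic box and the fixed 4-spheres-per-twitcher
topology (sphere ``4g`` tail, ``4g+3`` head).

The integrator is the Gronbech-Jensen/Farago discretisation of the
underdamped Langevin equation ``m x'' = -zeta x' - grad V + xi``, which
treats the linear drag exactly and injects Gaussian noise of variance
``2 zeta k_B T dt`` per step and component.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Motility phase codes (match twitchsim.params.Phase)
PH_REST = 0
PH_EXT = 1
PH_RETR = 2

# Kernel event codes
EV_ARRIVE = 2
EV_SNAP = 3
EV_EXHAUST = 4

# Kernel error codes
ERR_NONE = 0
ERR_OVERSTRETCH = 1
ERR_DEGENERATE = 2


@njit(cache=True)
def build_pairs(pos, box_L, rlist, use_cells, head, nxt, ncell,
                pairs_i, pairs_j):
    """Collect all sphere pairs within ``rlist`` (cut-off plus skin).

    Returns the pair count, or -1 if the pre-allocated buffers are too
    small.
    """
    n = pos.shape[0]
    cap = pairs_i.shape[0]
    rl2 = rlist * rlist
    npair = 0
    if use_cells:
        build_cells(pos, box_L, ncell, head, nxt)
        for cx in range(ncell):
            for cy in range(ncell):
                c = cx * ncell + cy
                i = head[c]
                while i >= 0:
                    j = nxt[i]
                    while j >= 0:
                        dx = _mi(pos[i, 0] - pos[j, 0], box_L)
                        dy = _mi(pos[i, 1] - pos[j, 1], box_L)
                        if dx * dx + dy * dy < rl2:
                            if npair >= cap:
                                return -1
                            pairs_i[npair] = i
                            pairs_j[npair] = j
                            npair += 1
                        j = nxt[j]
                    for s in range(4):
                        if s == 0:
                            ox, oy = 1, 0
                        elif s == 1:
                            ox, oy = 1, 1
                        elif s == 2:
                            ox, oy = 0, 1
                        else:
                            ox, oy = -1, 1
                        c2 = ((cx + ox) % ncell) * ncell + (cy + oy) % ncell
                        j = head[c2]
                        while j >= 0:
                            dx = _mi(pos[i, 0] - pos[j, 0], box_L)
                            dy = _mi(pos[i, 1] - pos[j, 1], box_L)
                            if dx * dx + dy * dy < rl2:
                                if npair >= cap:
                                    return -1
                                pairs_i[npair] = i
                                pairs_j[npair] = j
                                npair += 1
                            j = nxt[j]
                    i = nxt[i]
    else:
        for i in range(n):
            for j in range(i + 1, n):
                dx = _mi(pos[i, 0] - pos[j, 0], box_L)
                dy = _mi(pos[i, 1] - pos[j, 1], box_L)
                if dx * dx + dy * dy < rl2:
                    if npair >= cap:
                        return -1
                    pairs_i[npair] = i
                    pairs_j[npair] = j
                    npair += 1
    return npair


@njit(inline="always")
def _bonded_and_pilus(pos, f, box_L, phase, anchor,
                      kF, R0, kH, theta0, kP, r0p):
    """Add FENE, angle and pilus forces; returns an error code."""
    n = pos.shape[0]
    ntw = n // 4
    for g in range(ntw):
        base = 4 * g
        for k in range(3):
            i = base + k
            j = base + k + 1
            dx = _mi(pos[j, 0] - pos[i, 0], box_L)
            dy = _mi(pos[j, 1] - pos[i, 1], box_L)
            r2 = dx * dx + dy * dy
            if r2 >= R0 * R0:
                return ERR_OVERSTRETCH
            coef = kF / (1.0 - r2 / (R0 * R0))
            f[i, 0] += coef * dx
            f[i, 1] += coef * dy
            f[j, 0] -= coef * dx
            f[j, 1] -= coef * dy
        for k in range(2):
            i = base + k
            j = base + k + 1
            l = base + k + 2
            d1x = _mi(pos[i, 0] - pos[j, 0], box_L)
            d1y = _mi(pos[i, 1] - pos[j, 1], box_L)
            d2x = _mi(pos[l, 0] - pos[j, 0], box_L)
            d2y = _mi(pos[l, 1] - pos[j, 1], box_L)
            r1s = d1x * d1x + d1y * d1y
            r2s = d2x * d2x + d2y * d2y
            if r1s <= 0.0 or r2s <= 0.0:
                return ERR_DEGENERATE
            r1 = np.sqrt(r1s)
            r2_ = np.sqrt(r2s)
            c = (d1x * d2x + d1y * d2y) / (r1 * r2_)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            s = np.sqrt(1.0 - c * c)
            if s < 1e-12:
                s = 1e-12
            theta = np.arccos(c)
            a = kH * (theta - theta0) / s
            fi_x = a * (d2x / (r1 * r2_) - c * d1x / r1s)
            fi_y = a * (d2y / (r1 * r2_) - c * d1y / r1s)
            fl_x = a * (d1x / (r1 * r2_) - c * d2x / r2s)
            fl_y = a * (d1y / (r1 * r2_) - c * d2y / r2s)
            f[i, 0] += fi_x
            f[i, 1] += fi_y
            f[l, 0] += fl_x
            f[l, 1] += fl_y
            f[j, 0] -= fi_x + fl_x
            f[j, 1] -= fi_y + fl_y
    for g in range(ntw):
        if phase[g] == PH_RETR:
            h = 4 * g + 3
            dx = _mi(anchor[g, 0] - pos[h, 0], box_L)
            dy = _mi(anchor[g, 1] - pos[h, 1], box_L)
            r = np.sqrt(dx * dx + dy * dy)
            if r > r0p:
                f[h, 0] += kP * dx / r
                f[h, 1] += kP * dy / r
    return ERR_NONE


@njit(inline="always")
def _forces_from_pairs(pos, f, box_L, phase, anchor, npair, pairs_i, pairs_j,
                       eps, sigma, rc, kF, R0, kH, theta0, kP, r0p):
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
    rc2 = rc * rc
    for k in range(npair):
        i = pairs_i[k]
        j = pairs_j[k]
        dx = _mi(pos[i, 0] - pos[j, 0], box_L)
        dy = _mi(pos[i, 1] - pos[j, 1], box_L)
        r2 = dx * dx + dy * dy
        if r2 < rc2:
            s2 = sigma * sigma / r2
            s6 = s2 * s2 * s2
            fc = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
            f[i, 0] += fc * dx
            f[i, 1] += fc * dy
            f[j, 0] -= fc * dx
            f[j, 1] -= fc * dy
    return _bonded_and_pilus(pos, f, box_L, phase, anchor,
                             kF, R0, kH, theta0, kP, r0p)


@njit(inline="always")
def _mi(d, box_L):
    # wrapped coordinates differ by less than one box length, so a
    # single branch replaces the generic round(d/L) construction
    if d > 0.5 * box_L:
        return d - box_L
    if d < -0.5 * box_L:
        return d + box_L
    return d


@njit(inline="always")
def _wca_fcoef(r2, eps, sigma, rc):
    """Return F/r for the WCA pair force at squared separation r2."""
    if r2 >= rc * rc:
        return 0.0
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    return 24.0 * eps * (2.0 * s6 * s6 - s6) / r2


@njit(cache=True)
def build_cells(pos, box_L, ncell, head, nxt):
    n = pos.shape[0]
    for c in range(ncell * ncell):
        head[c] = -1
    inv = ncell / box_L
    for i in range(n):
        cx = int(pos[i, 0] * inv)
        cy = int(pos[i, 1] * inv)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        c = cx * ncell + cy
        nxt[i] = head[c]
        head[c] = i


@njit(cache=True)
def compute_forces(pos, f, box_L, phase, anchor,
                   eps, sigma, rc, kF, R0, kH, theta0, kP, r0p,
                   use_cells, head, nxt, ncell):
    """Fill ``f`` with the total conservative force on every sphere.

    Returns an error code (0 ok, 1 FENE bond overstretched, 2 degenerate
    geometry).
    """
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0

    # --- WCA excluded volume between all sphere pairs -----------------
    if use_cells:
        build_cells(pos, box_L, ncell, head, nxt)
        # half-neighbour stencil in 2D
        for cx in range(ncell):
            for cy in range(ncell):
                c = cx * ncell + cy
                i = head[c]
                while i >= 0:
                    # same cell, j after i in the list
                    j = nxt[i]
                    while j >= 0:
                        dx = _mi(pos[i, 0] - pos[j, 0], box_L)
                        dy = _mi(pos[i, 1] - pos[j, 1], box_L)
                        r2 = dx * dx + dy * dy
                        fc = _wca_fcoef(r2, eps, sigma, rc)
                        if fc != 0.0:
                            f[i, 0] += fc * dx
                            f[i, 1] += fc * dy
                            f[j, 0] -= fc * dx
                            f[j, 1] -= fc * dy
                        j = nxt[j]
                    # half stencil neighbour cells
                    for s in range(4):
                        if s == 0:
                            ox, oy = 1, 0
                        elif s == 1:
                            ox, oy = 1, 1
                        elif s == 2:
                            ox, oy = 0, 1
                        else:
                            ox, oy = -1, 1
                        c2 = ((cx + ox) % ncell) * ncell + (cy + oy) % ncell
                        j = head[c2]
                        while j >= 0:
                            dx = _mi(pos[i, 0] - pos[j, 0], box_L)
                            dy = _mi(pos[i, 1] - pos[j, 1], box_L)
                            r2 = dx * dx + dy * dy
                            fc = _wca_fcoef(r2, eps, sigma, rc)
                            if fc != 0.0:
                                f[i, 0] += fc * dx
                                f[i, 1] += fc * dy
                                f[j, 0] -= fc * dx
                                f[j, 1] -= fc * dy
                            j = nxt[j]
                    i = nxt[i]
    else:
        for i in range(n):
            for j in range(i + 1, n):
                dx = _mi(pos[i, 0] - pos[j, 0], box_L)
                dy = _mi(pos[i, 1] - pos[j, 1], box_L)
                r2 = dx * dx + dy * dy
                fc = _wca_fcoef(r2, eps, sigma, rc)
                if fc != 0.0:
                    f[i, 0] += fc * dx
                    f[i, 1] += fc * dy
                    f[j, 0] -= fc * dx
                    f[j, 1] -= fc * dy

    # --- FENE bonds, harmonic angles and pilus forces ------------------
    return _bonded_and_pilus(pos, f, box_L, phase, anchor,
                             kF, R0, kH, theta0, kP, r0p)


@njit(cache=True)
def total_energy(pos, box_L, phase, anchor,
                 eps, sigma, rc, kF, R0, kH, theta0, kP, r0p):
    """Total potential energy (WCA + FENE + angle + pilus)."""
    n = pos.shape[0]
    ntw = n // 4
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _mi(pos[i, 0] - pos[j, 0], box_L)
            dy = _mi(pos[i, 1] - pos[j, 1], box_L)
            r2 = dx * dx + dy * dy
            if r2 < rc * rc:
                s2 = sigma * sigma / r2
                s6 = s2 * s2 * s2
                e += 4.0 * eps * (s6 * s6 - s6) + eps
    for g in range(ntw):
        base = 4 * g
        for k in range(3):
            i = base + k
            j = base + k + 1
            dx = _mi(pos[j, 0] - pos[i, 0], box_L)
            dy = _mi(pos[j, 1] - pos[i, 1], box_L)
            r2 = dx * dx + dy * dy
            e += -0.5 * kF * R0 * R0 * np.log(1.0 - r2 / (R0 * R0))
        for k in range(2):
            i = base + k
            j = base + k + 1
            l = base + k + 2
            d1x = _mi(pos[i, 0] - pos[j, 0], box_L)
            d1y = _mi(pos[i, 1] - pos[j, 1], box_L)
            d2x = _mi(pos[l, 0] - pos[j, 0], box_L)
            d2y = _mi(pos[l, 1] - pos[j, 1], box_L)
            r1 = np.sqrt(d1x * d1x + d1y * d1y)
            r2_ = np.sqrt(d2x * d2x + d2y * d2y)
            c = (d1x * d2x + d1y * d2y) / (r1 * r2_)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            theta = np.arccos(c)
            e += 0.5 * kH * (theta - theta0) ** 2
    for g in range(ntw):
        if phase[g] == PH_RETR:
            h = 4 * g + 3
            dx = _mi(anchor[g, 0] - pos[h, 0], box_L)
            dy = _mi(anchor[g, 1] - pos[h, 1], box_L)
            r = np.sqrt(dx * dx + dy * dy)
            if r > r0p:
                e += kP * (r - r0p)
    return e


@njit(cache=True)
def advance(pos, posu, vel, f0, f1, phase, anchor, retr_clock,
            nsteps, step0, noise,
            box_L, dt, m, zeta, kT,
            eps, sigma, rc, skin, kF, R0, kH, theta0, kP, r0p,
            LR, LS, tM_steps,
            use_cells, head, nxt, ncell,
            pairs_i, pairs_j, pair_ref,
            ev_tid, ev_kind, ev_step):
    """Advance ``nsteps`` integration steps.

    ``noise`` holds pre-drawn standard normals of shape (nsteps, n, 2);
    they are scaled by the fluctuation-dissipation amplitude
    ``sqrt(2 zeta kT dt)`` here.  Pair interactions use a Verlet list
    with the given skin, rebuilt whenever any sphere has moved more
    than half the skin since the last build.

    Retraction termination (arrive < snap < exhaust priority) is checked
    after every step; terminated twitchers drop their anchor and return
    to rest immediately.  Events are written into the ``ev_*`` buffers.

    Returns ``(n_events, error_code, error_step)``.
    """
    n = pos.shape[0]
    ntw = n // 4
    denom = 1.0 + zeta * dt / (2.0 * m)
    bco = 1.0 / denom
    aco = (1.0 - zeta * dt / (2.0 * m)) / denom
    std = np.sqrt(2.0 * zeta * kT * dt)
    c1 = bco * dt
    c2 = bco * dt * dt / (2.0 * m)
    c3 = bco * dt / (2.0 * m) * std
    c4 = dt / (2.0 * m)
    c5 = bco / m * std
    half_skin2 = (0.5 * skin) ** 2

    nev = 0
    npair = build_pairs(pos, box_L, rc + skin, use_cells, head, nxt, ncell,
                        pairs_i, pairs_j)
    if npair < 0:
        return nev, ERR_DEGENERATE, step0
    for i in range(n):
        pair_ref[i, 0] = pos[i, 0]
        pair_ref[i, 1] = pos[i, 1]
    err = _forces_from_pairs(pos, f0, box_L, phase, anchor, npair,
                             pairs_i, pairs_j,
                             eps, sigma, rc, kF, R0, kH, theta0, kP, r0p)
    if err != ERR_NONE:
        return nev, err, step0

    for step in range(nsteps):
        moved = False
        for i in range(n):
            for d in range(2):
                beta = noise[step, i, d]
                dx = c1 * vel[i, d] + c2 * f0[i, d] + c3 * beta
                posu[i, d] += dx
                x = pos[i, d] + dx
                if x >= box_L:
                    x -= box_L
                elif x < 0.0:
                    x += box_L
                pos[i, d] = x
                vel[i, d] = aco * vel[i, d] + c4 * aco * f0[i, d] + c5 * beta
            rx = _mi(pos[i, 0] - pair_ref[i, 0], box_L)
            ry = _mi(pos[i, 1] - pair_ref[i, 1], box_L)
            if rx * rx + ry * ry > half_skin2:
                moved = True
        if moved:
            npair = build_pairs(pos, box_L, rc + skin, use_cells, head, nxt,
                                ncell, pairs_i, pairs_j)
            if npair < 0:
                return nev, ERR_DEGENERATE, step0 + step + 1
            for i in range(n):
                pair_ref[i, 0] = pos[i, 0]
                pair_ref[i, 1] = pos[i, 1]
        err = _forces_from_pairs(pos, f1, box_L, phase, anchor, npair,
                                 pairs_i, pairs_j,
                                 eps, sigma, rc, kF, R0, kH, theta0, kP, r0p)
        if err != ERR_NONE:
            return nev, err, step0 + step + 1
        for i in range(n):
            vel[i, 0] += c4 * f1[i, 0]
            vel[i, 1] += c4 * f1[i, 1]
            f0[i, 0] = f1[i, 0]
            f0[i, 1] = f1[i, 1]
        # retraction termination checks, every integration step
        for g in range(ntw):
            if phase[g] == PH_RETR:
                retr_clock[g] += 1
                h = 4 * g + 3
                dxs = _mi(anchor[g, 0] - pos[h, 0], box_L)
                dys = _mi(anchor[g, 1] - pos[h, 1], box_L)
                r = np.sqrt(dxs * dxs + dys * dys)
                kind = -1
                if r < LR:
                    kind = EV_ARRIVE
                elif r > LS:
                    kind = EV_SNAP
                elif retr_clock[g] >= tM_steps:
                    kind = EV_EXHAUST
                if kind >= 0:
                    phase[g] = PH_REST
                    anchor[g, 0] = np.nan
                    anchor[g, 1] = np.nan
                    retr_clock[g] = 0
                    if nev < ev_tid.shape[0]:
                        ev_tid[nev] = g
                        ev_kind[nev] = kind
                        ev_step[nev] = step0 + step + 1
                        nev += 1
    return nev, ERR_NONE, 0
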