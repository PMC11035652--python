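"""Numba kernels for the single-type Lennard-Jones NVT/NVE engine.

The fast path covers atomic LJ systems in reduced units (the vapor /
liquid / solid state-point simulations): half Verlet neighbor lists built
from linked cells, minimum-image truncated LJ forces, and a BAOAB Langevin
integrator that reduces to velocity Verlet when the friction is zero.
Positions are kept wrapped with integer image flags so the minimum-image
correction is a single branch instead of a rounded division.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def neighbor_list(xw, box, rlist):
    """Half neighbor list within rlist for wrapped coords, as flat (i, j).

    Linked cells with a 13-offset half stencil, single sweep into a grown-
    on-demand pair buffer; falls back to all-pairs for boxes under three
    cells per edge.
    """
    n = xw.shape[0]
    rl2 = rlist * rlist
    hb0, hb1, hb2 = 0.5 * box[0], 0.5 * box[1], 0.5 * box[2]
    b0, b1, b2 = box[0], box[1], box[2]
    nc0 = max(1, int(box[0] / rlist))
    nc1 = max(1, int(box[1] / rlist))
    nc2 = max(1, int(box[2] / rlist))
    use_cells = nc0 >= 3 and nc1 >= 3 and nc2 >= 3

    # generous capacity estimate; grown and retried on overflow
    vol = b0 * b1 * b2
    est = int(0.75 * n * n * 4.1888 * rlist ** 3 / vol) + 16 * n + 64
    while True:
        pi = np.empty(est, dtype=np.int32)
        pj = np.empty(est, dtype=np.int32)
        m = 0
        overflow = False
        if not use_cells:
            for i in range(n - 1):
                for j in range(i + 1, n):
                    d0 = xw[i, 0] - xw[j, 0]
                    if d0 > hb0:
                        d0 -= b0
                    elif d0 < -hb0:
                        d0 += b0
                    d1 = xw[i, 1] - xw[j, 1]
                    if d1 > hb1:
                        d1 -= b1
                    elif d1 < -hb1:
                        d1 += b1
                    d2 = xw[i, 2] - xw[j, 2]
                    if d2 > hb2:
                        d2 -= b2
                    elif d2 < -hb2:
                        d2 += b2
                    if d0 * d0 + d1 * d1 + d2 * d2 < rl2:
                        if m >= est:
                            overflow = True
                            break
                        pi[m] = i
                        pj[m] = j
                        m += 1
                if overflow:
                    break
        else:
            ncell = nc0 * nc1 * nc2
            cell_of = np.empty(n, dtype=np.int64)
            for i in range(n):
                cx = min(int(xw[i, 0] / b0 * nc0), nc0 - 1)
                cy = min(int(xw[i, 1] / b1 * nc1), nc1 - 1)
                cz = min(int(xw[i, 2] / b2 * nc2), nc2 - 1)
                if cx < 0:
                    cx = 0
                if cy < 0:
                    cy = 0
                if cz < 0:
                    cz = 0
                cell_of[i] = (cx * nc1 + cy) * nc2 + cz
            start = np.zeros(ncell + 1, dtype=np.int64)
            for i in range(n):
                start[cell_of[i] + 1] += 1
            for c in range(ncell):
                start[c + 1] += start[c]
            order = np.empty(n, dtype=np.int32)
            fill_c = np.zeros(ncell, dtype=np.int64)
            for i in range(n):
                c = cell_of[i]
                order[start[c] + fill_c[c]] = i
                fill_c[c] += 1
            # 13 canonical half-stencil offsets + intra-cell i<j pairs
            offs = np.array([
                (1, -1, -1), (1, -1, 0), (1, -1, 1),
                (1, 0, -1), (1, 0, 0), (1, 0, 1),
                (1, 1, -1), (1, 1, 0), (1, 1, 1),
                (0, 1, -1), (0, 1, 0), (0, 1, 1),
                (0, 0, 1)], dtype=np.int64)
            for ca in range(ncell):
                cx = ca // (nc1 * nc2)
                cy = (ca // nc2) % nc1
                cz = ca % nc2
                a0, a1 = start[ca], start[ca + 1]
                # intra-cell
                for sa in range(a0, a1):
                    i = order[sa]
                    xi0 = xw[i, 0]
                    xi1 = xw[i, 1]
                    xi2 = xw[i, 2]
                    for sb in range(sa + 1, a1):
                        j = order[sb]
                        d0 = xi0 - xw[j, 0]
                        if d0 > hb0:
                            d0 -= b0
                        elif d0 < -hb0:
                            d0 += b0
                        d1 = xi1 - xw[j, 1]
                        if d1 > hb1:
                            d1 -= b1
                        elif d1 < -hb1:
                            d1 += b1
                        d2 = xi2 - xw[j, 2]
                        if d2 > hb2:
                            d2 -= b2
                        elif d2 < -hb2:
                            d2 += b2
                        if d0 * d0 + d1 * d1 + d2 * d2 < rl2:
                            if m >= est:
                                overflow = True
                                break
                            if i < j:
                                pi[m] = i
                                pj[m] = j
                            else:
                                pi[m] = j
                                pj[m] = i
                            m += 1
                    if overflow:
                        break
                if overflow:
                    break
                # neighbor cells
                for o in range(13):
                    jx = (cx + offs[o, 0]) % nc0
                    jy = (cy + offs[o, 1]) % nc1
                    jz = (cz + offs[o, 2]) % nc2
                    cb = (jx * nc1 + jy) * nc2 + jz
                    b_0, b_1 = start[cb], start[cb + 1]
                    for sa in range(a0, a1):
                        i = order[sa]
                        xi0 = xw[i, 0]
                        xi1 = xw[i, 1]
                        xi2 = xw[i, 2]
                        for sb in range(b_0, b_1):
                            j = order[sb]
                            d0 = xi0 - xw[j, 0]
                            if d0 > hb0:
                                d0 -= b0
                            elif d0 < -hb0:
                                d0 += b0
                            d1 = xi1 - xw[j, 1]
                            if d1 > hb1:
                                d1 -= b1
                            elif d1 < -hb1:
                                d1 += b1
                            d2 = xi2 - xw[j, 2]
                            if d2 > hb2:
                                d2 -= b2
                            elif d2 < -hb2:
                                d2 += b2
                            if d0 * d0 + d1 * d1 + d2 * d2 < rl2:
                                if m >= est:
                                    overflow = True
                                    break
                                if i < j:
                                    pi[m] = i
                                    pj[m] = j
                                else:
                                    pi[m] = j
                                    pj[m] = i
                                m += 1
                        if overflow:
                            break
                    if overflow:
                        break
                if overflow:
                    break
        if not overflow:
            return pi[:m].copy(), pj[:m].copy()
        est *= 2


@njit(cache=True, fastmath=True)
def lj_forces(xw, box, pi, pj, rc, shift, f, fx, fy, fz):
    """LJ forces from a flat half pair list; returns potential energy.

    Two passes: a vectorizable sweep computing per-pair force components
    into the ``fx/fy/fz`` scratch buffers, then a scalar scatter
    accumulation into ``f``.
    """
    npair = pi.shape[0]
    n = xw.shape[0]
    rc2 = rc * rc
    src6 = 1.0 / rc2 ** 3
    eshift = 4.0 * (src6 * src6 - src6) if shift else 0.0
    hb0, hb1, hb2 = 0.5 * box[0], 0.5 * box[1], 0.5 * box[2]
    b0, b1, b2 = box[0], box[1], box[2]
    epot = 0.0
    for s in range(npair):
        i = pi[s]
        j = pj[s]
        d0 = xw[i, 0] - xw[j, 0]
        if d0 > hb0:
            d0 -= b0
        elif d0 < -hb0:
            d0 += b0
        d1 = xw[i, 1] - xw[j, 1]
        if d1 > hb1:
            d1 -= b1
        elif d1 < -hb1:
            d1 += b1
        d2 = xw[i, 2] - xw[j, 2]
        if d2 > hb2:
            d2 -= b2
        elif d2 < -hb2:
            d2 += b2
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        ir2 = 1.0 / r2
        sr6 = ir2 * ir2 * ir2
        e = 4.0 * (sr6 * sr6 - sr6) - eshift
        fpair = 24.0 * (2.0 * sr6 * sr6 - sr6) * ir2
        if r2 >= rc2:
            e = 0.0
            fpair = 0.0
        epot += e
        fx[s] = fpair * d0
        fy[s] = fpair * d1
        fz[s] = fpair * d2
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    for s in range(npair):
        i = pi[s]
        j = pj[s]
        f[i, 0] += fx[s]
        f[i, 1] += fy[s]
        f[i, 2] += fz[s]
        f[j, 0] -= fx[s]
        f[j, 1] -= fy[s]
        f[j, 2] -= fz[s]
    return epot


@njit(cache=True, fastmath=True)
def _cell_order(xw, box, rlist):
    """Particle permutation grouping by linked cell (cache locality)."""
    n = xw.shape[0]
    nc0 = max(1, int(box[0] / rlist))
    nc1 = max(1, int(box[1] / rlist))
    nc2 = max(1, int(box[2] / rlist))
    ncell = nc0 * nc1 * nc2
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = min(max(int(xw[i, 0] / box[0] * nc0), 0), nc0 - 1)
        cy = min(max(int(xw[i, 1] / box[1] * nc1), 0), nc1 - 1)
        cz = min(max(int(xw[i, 2] / box[2] * nc2), 0), nc2 - 1)
        cell_of[i] = (cx * nc1 + cy) * nc2 + cz
    start = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        start[cell_of[i] + 1] += 1
    for c in range(ncell):
        start[c + 1] += start[c]
    order = np.empty(n, dtype=np.int64)
    fill = np.zeros(ncell, dtype=np.int64)
    for i in range(n):
        c = cell_of[i]
        order[start[c] + fill[c]] = i
        fill[c] += 1
    return order


@njit(cache=True, fastmath=True)
def run_lj_block(xw, img, v, ids, box, dt, c1, c2, noise, n_steps,
                 rc, skin, shift):
    """Integrate ``n_steps`` BAOAB/velocity-Verlet steps in place.

    ``xw`` (wrapped positions), ``img`` (image flags), ``v`` and ``ids``
    (original particle ids, for unscrambling dumps) are mutated in place;
    the caller supplies pre-generated unit normals ``noise`` of shape
    (n_steps, N, 3) for the Langevin O-step (empty array for NVE).
    Returns the potential energy after the last step.
    """
    n = xw.shape[0]
    f = np.zeros((n, 3))
    rlist = rc + skin
    tmp = np.empty((n, 3))
    itmp = np.empty((n, 3), dtype=np.int64)
    ktmp = np.empty(n, dtype=np.int64)

    order = _cell_order(xw, box, rlist)
    _permute(xw, v, img, ids, order, tmp, itmp, ktmp)
    pi, pj = neighbor_list(xw, box, rlist)
    fx = np.empty(pi.shape[0])
    fy = np.empty(pi.shape[0])
    fz = np.empty(pi.shape[0])
    xr = xw.copy()
    epot = lj_forces(xw, box, pi, pj, rc, shift, f, fx, fy, fz)

    half = 0.5 * dt
    skin_half2 = (0.5 * skin) ** 2
    hb0, hb1, hb2 = 0.5 * box[0], 0.5 * box[1], 0.5 * box[2]
    langevin = noise.shape[0] > 0

    for step in range(n_steps):
        for i in range(n):
            v[i, 0] += half * f[i, 0]
            v[i, 1] += half * f[i, 1]
            v[i, 2] += half * f[i, 2]
            xw[i, 0] += half * v[i, 0]
            xw[i, 1] += half * v[i, 1]
            xw[i, 2] += half * v[i, 2]
        if langevin:
            for i in range(n):
                v[i, 0] = c1 * v[i, 0] + c2 * noise[step, i, 0]
                v[i, 1] = c1 * v[i, 1] + c2 * noise[step, i, 1]
                v[i, 2] = c1 * v[i, 2] + c2 * noise[step, i, 2]
        for i in range(n):
            for d in range(3):
                xw[i, d] += half * v[i, d]
                if xw[i, d] >= box[d]:
                    xw[i, d] -= box[d]
                    img[i, d] += 1
                elif xw[i, d] < 0.0:
                    xw[i, d] += box[d]
                    img[i, d] -= 1
        # refresh neighbor list when any particle moved more than skin/2
        maxd2 = 0.0
        for i in range(n):
            d0 = xw[i, 0] - xr[i, 0]
            if d0 > hb0:
                d0 -= box[0]
            elif d0 < -hb0:
                d0 += box[0]
            d1 = xw[i, 1] - xr[i, 1]
            if d1 > hb1:
                d1 -= box[1]
            elif d1 < -hb1:
                d1 += box[1]
            d2 = xw[i, 2] - xr[i, 2]
            if d2 > hb2:
                d2 -= box[2]
            elif d2 < -hb2:
                d2 += box[2]
            dd = d0 * d0 + d1 * d1 + d2 * d2
            if dd > maxd2:
                maxd2 = dd
        if maxd2 > skin_half2:
            order = _cell_order(xw, box, rlist)
            _permute(xw, v, img, ids, order, tmp, itmp, ktmp)
            pi, pj = neighbor_list(xw, box, rlist)
            if pi.shape[0] > fx.shape[0]:
                fx = np.empty(pi.shape[0])
                fy = np.empty(pi.shape[0])
                fz = np.empty(pi.shape[0])
            xr[:] = xw
        epot = lj_forces(xw, box, pi, pj, rc, shift, f, fx, fy, fz)
        for i in range(n):
            v[i, 0] += half * f[i, 0]
            v[i, 1] += half * f[i, 1]
            v[i, 2] += half * f[i, 2]
    return epot


@njit(cache=True, fastmath=True)
def _permute(xw, v, img, ids, order, tmp, itmp, ktmp):
    n = xw.shape[0]
    for arr, buf in ((xw, tmp), (v, tmp)):
        for i in range(n):
            o = order[i]
            buf[i, 0] = arr[o, 0]
            buf[i, 1] = arr[o, 1]
            buf[i, 2] = arr[o, 2]
        arr[:] = buf
    for i in range(n):
        o = order[i]
        itmp[i, 0] = img[o, 0]
        itmp[i, 1] = img[o, 1]
        itmp[i, 2] = img[o, 2]
        ktmp[i] = ids[o]
    img[:] = itmp
    ids[:] = ktmp
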