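"""Compiled inner loop of the crankshaft Monte Carlo engine.

All heavy per-move work lives here: proposal generation, the Rodrigues
rotation, the hard-wall and hard-core tests through a linked-cell
neighbour list, and the displacement-bounded swept-path substeps that
prevent chain crossing.  The Python layer (:mod:`ringmix.mc`) owns
scheduling, sampling and audits.

The kernel draws every random number from numba's internal global RNG,
seeded once per run via :func:`seed_rng`; a fixed seed therefore fixes
the whole trajectory bit for bit.
"""

import numpy as np
from numba import njit

__all__ = ["seed_rng", "build_cells", "run_chunk"]


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _inside_wall(x, y, z, r2_limit, zc):
    az = abs(z)
    rho2 = x * x + y * y
    if az <= zc:
        return rho2 <= r2_limit
    dz = az - zc
    return rho2 + dz * dz <= r2_limit


@njit(cache=True, inline="always")
def _cell_index(x, y, z, x0, z0, inv_e, ncx, ncy, ncz):
    cx = int((x - x0) * inv_e)
    cy = int((y - x0) * inv_e)
    cz = int((z - z0) * inv_e)
    if cx < 0:
        cx = 0
    elif cx >= ncx:
        cx = ncx - 1
    if cy < 0:
        cy = 0
    elif cy >= ncy:
        cy = ncy - 1
    if cz < 0:
        cz = 0
    elif cz >= ncz:
        cz = ncz - 1
    return (cz * ncy + cy) * ncx + cx


@njit(cache=True)
def build_cells(pos, x0, z0, inv_e, ncx, ncy, ncz, head, nxt, cell_of):
    head[:] = -1
    for b in range(pos.shape[0]):
        c = _cell_index(pos[b, 0], pos[b, 1], pos[b, 2],
                        x0, z0, inv_e, ncx, ncy, ncz)
        cell_of[b] = c
        nxt[b] = head[c]
        head[c] = b


@njit(cache=True, inline="always")
def _bonded(g, q, start1, n0, n1, circ0, circ1):
    if g < start1:
        if q >= start1:
            return False
        d = g - q if g > q else q - g
        return d == 1 or (circ0 == 1 and d == n0 - 1)
    if q < start1:
        return False
    d = g - q if g > q else q - g
    return d == 1 or (circ1 == 1 and d == n1 - 1)


@njit(cache=True)
def _collides(px, py, pz, g, restrict_other, c_moved, start1,
              n0, n1, circ0, circ1, pos, moved_flag, rr2,
              x0, z0, inv_e, ncx, ncy, ncz, head, nxt):
    """Hard-core test of a trial point against static beads.

    ``restrict_other`` != 0 limits candidates to topology partners during
    swept-path substeps: the moved chain itself plus, when the flag is 2,
    the other chain as well.
    """
    cx = int((px - x0) * inv_e)
    cy = int((py - x0) * inv_e)
    cz = int((pz - z0) * inv_e)
    if cx < 0:
        cx = 0
    elif cx >= ncx:
        cx = ncx - 1
    if cy < 0:
        cy = 0
    elif cy >= ncy:
        cy = ncy - 1
    if cz < 0:
        cz = 0
    elif cz >= ncz:
        cz = ncz - 1
    for dx in range(-1, 2):
        ax = cx + dx
        if ax < 0 or ax >= ncx:
            continue
        for dy in range(-1, 2):
            ay = cy + dy
            if ay < 0 or ay >= ncy:
                continue
            for dz in range(-1, 2):
                az = cz + dz
                if az < 0 or az >= ncz:
                    continue
                q = head[(az * ncy + ay) * ncx + ax]
                while q >= 0:
                    if moved_flag[q] == 0:
                        ok = True
                        if restrict_other == 1:
                            in_c1 = q >= start1
                            if (1 if in_c1 else 0) != c_moved:
                                ok = False
                        if ok and not _bonded(g, q, start1, n0, n1,
                                              circ0, circ1):
                            ddx = px - pos[q, 0]
                            ddy = py - pos[q, 1]
                            ddz = pz - pos[q, 2]
                            if ddx * ddx + ddy * ddy + ddz * ddz < rr2:
                                return True
                    q = nxt[q]
    return False


@njit(cache=True, inline="always")
def _rotate_one(x, y, z, ax, ay, az, ux, uy, uz, c, s):
    px = x - ax
    py = y - ay
    pz = z - az
    dot = px * ux + py * uy + pz * uz
    crx = uy * pz - uz * py
    cry = uz * px - ux * pz
    crz = ux * py - uy * px
    omc = 1.0 - c
    rx = px * c + crx * s + ux * dot * omc
    ry = py * c + cry * s + uy * dot * omc
    rz = pz * c + crz * s + uz * dot * omc
    return rx + ax, ry + ay, rz + az


@njit(cache=True)
def _cells_update(b, px, py, pz, x0, z0, inv_e, ncx, ncy, ncz,
                  head, nxt, cell_of):
    old = cell_of[b]
    new = _cell_index(px, py, pz, x0, z0, inv_e, ncx, ncy, ncz)
    if new == old:
        return
    q = head[old]
    if q == b:
        head[old] = nxt[b]
    else:
        while nxt[q] != b:
            q = nxt[q]
        nxt[q] = nxt[b]
    nxt[b] = head[new]
    head[new] = b
    cell_of[b] = new


@njit(cache=True)
def run_chunk(pos, start1, n0, n1, circ0, circ1,
              r, rr2, wall_r2, zc,
              s_max, theta_max, sweep0, sweep1, sweep_other,
              trans_prob, trans_max,
              n_iter,
              x0, z0, inv_e, ncx, ncy, ncz, head, nxt, cell_of,
              moved, newpos, moved_flag):
    """Attempt ``n_iter`` Monte Carlo moves in place; returns the number
    accepted.  ``sweep0``/``sweep1`` mark chains whose moves need the
    swept-path crossing check; ``sweep_other`` widens that check to the
    partner chain (two-ring systems, where linking is conserved)."""
    accepted = 0
    n_total = pos.shape[0]

    for _ in range(n_iter):
        is_translation = False
        if trans_prob > 0.0:
            if np.random.random() < trans_prob:
                is_translation = True

        c = np.random.randint(0, 2)
        if c == 0:
            st = 0
            n = n0
            circ_c = circ0
            sweep_c = sweep0
        else:
            st = start1
            n = n1
            circ_c = circ1
            sweep_c = sweep1

        if is_translation:
            # Rigid translation of the whole chain (optional move; off by
            # default).  Intra-chain geometry is preserved, so only the
            # wall and cross-chain hard core are tested.
            dx = 2.0
            dy = 0.0
            dz = 0.0
            while dx * dx + dy * dy + dz * dz > 1.0:
                dx = 2.0 * np.random.random() - 1.0
                dy = 2.0 * np.random.random() - 1.0
                dz = 2.0 * np.random.random() - 1.0
            dx *= trans_max
            dy *= trans_max
            dz *= trans_max
            ok = True
            for t in range(n):
                b = st + t
                px = pos[b, 0] + dx
                py = pos[b, 1] + dy
                pz = pos[b, 2] + dz
                if not _inside_wall(px, py, pz, wall_r2, zc):
                    ok = False
                    break
                newpos[t, 0] = px
                newpos[t, 1] = py
                newpos[t, 2] = pz
            if ok:
                for t in range(n):
                    moved_flag[st + t] = 1
                for t in range(n):
                    if _collides(newpos[t, 0], newpos[t, 1], newpos[t, 2],
                                 st + t, 0, c, start1, n0, n1, circ0, circ1,
                                 pos, moved_flag, rr2, x0, z0, inv_e,
                                 ncx, ncy, ncz, head, nxt):
                        ok = False
                        break
                if ok and sweep_c == 1 and sweep_other == 1:
                    step = np.sqrt(dx * dx + dy * dy + dz * dz)
                    nsub = int(np.ceil(step / (0.999 * r)))
                    for k in range(1, nsub):
                        f = k / nsub
                        for t in range(n):
                            b = st + t
                            if _collides(pos[b, 0] + dx * f, pos[b, 1] + dy * f,
                                         pos[b, 2] + dz * f, b, 0, c, start1,
                                         n0, n1, circ0, circ1, pos, moved_flag,
                                         rr2, x0, z0, inv_e, ncx, ncy, ncz,
                                         head, nxt):
                                ok = False
                                break
                        if not ok:
                            break
                for t in range(n):
                    moved_flag[st + t] = 0
            if ok:
                for t in range(n):
                    b = st + t
                    _cells_update(b, newpos[t, 0], newpos[t, 1], newpos[t, 2],
                                  x0, z0, inv_e, ncx, ncy, ncz,
                                  head, nxt, cell_of)
                    pos[b, 0] = newpos[t, 0]
                    pos[b, 1] = newpos[t, 1]
                    pos[b, 2] = newpos[t, 2]
                accepted += 1
            continue

        # --- crankshaft proposal ---
        i = np.random.randint(0, n)
        smx = n // 2
        if smx > s_max:
            smx = s_max
        if smx < 1:
            smx = 1
        s = np.random.randint(1, smx + 1)
        theta = (2.0 * np.random.random() - 1.0) * theta_max

        terminal = False
        nm = 0
        if circ_c == 1:
            j = (i + s) % n
            nm = s - 1
            for t in range(nm):
                moved[t] = st + ((i + 1 + t) % n)
            ai = st + i
            aj = st + j
            ax, ay, az = pos[ai, 0], pos[ai, 1], pos[ai, 2]
            ux = pos[aj, 0] - ax
            uy = pos[aj, 1] - ay
            uz = pos[aj, 2] - az
        else:
            d = 1 if np.random.random() < 0.5 else -1
            j = i + d * s
            if 0 <= j < n:
                lo = i if i < j else j
                hi = j if i < j else i
                nm = hi - lo - 1
                for t in range(nm):
                    moved[t] = st + lo + 1 + t
                ai = st + lo
                aj = st + hi
                ax, ay, az = pos[ai, 0], pos[ai, 1], pos[ai, 2]
                ux = pos[aj, 0] - ax
                uy = pos[aj, 1] - ay
                uz = pos[aj, 2] - az
            else:
                # Overshooting an end reflects into a terminal rotation of
                # every bead beyond the single interior pivot, about a
                # uniformly random axis through that pivot.
                terminal = True
                if j >= n:
                    p = 2 * (n - 1) - j
                    nm = n - 1 - p
                    for t in range(nm):
                        moved[t] = st + p + 1 + t
                else:
                    p = -j
                    nm = p
                    for t in range(nm):
                        moved[t] = st + t
                ai = st + p
                ax, ay, az = pos[ai, 0], pos[ai, 1], pos[ai, 2]
                ux = 0.0
                uy = 0.0
                uz = 0.0
                norm2 = 0.0
                while norm2 < 1e-24:
                    ux = np.random.standard_normal()
                    uy = np.random.standard_normal()
                    uz = np.random.standard_normal()
                    norm2 = ux * ux + uy * uy + uz * uz

        if nm == 0:
            accepted += 1  # rotating an empty segment is a no-op move
            continue

        norm = np.sqrt(ux * ux + uy * uy + uz * uz)
        ux /= norm
        uy /= norm
        uz /= norm

        ct = np.cos(theta)
        stheta = np.sin(theta)
        ok = True
        for t in range(nm):
            b = moved[t]
            px, py, pz = _rotate_one(pos[b, 0], pos[b, 1], pos[b, 2],
                                     ax, ay, az, ux, uy, uz, ct, stheta)
            if not _inside_wall(px, py, pz, wall_r2, zc):
                ok = False
                break
            newpos[t, 0] = px
            newpos[t, 1] = py
            newpos[t, 2] = pz

        if ok:
            for t in range(nm):
                moved_flag[moved[t]] = 1
            for t in range(nm):
                if _collides(newpos[t, 0], newpos[t, 1], newpos[t, 2],
                             moved[t], 0, c, start1, n0, n1, circ0, circ1,
                             pos, moved_flag, rr2, x0, z0, inv_e,
                             ncx, ncy, ncz, head, nxt):
                    ok = False
                    break

            if ok and sweep_c == 1:
                # Swept-path crossing check: substeps sized so the largest
                # bead displacement per substep stays below one radius.
                rmax2 = 0.0
                for t in range(nm):
                    b = moved[t]
                    px = pos[b, 0] - ax
                    py = pos[b, 1] - ay
                    pz = pos[b, 2] - az
                    dot = px * ux + py * uy + pz * uz
                    perp2 = (px * px + py * py + pz * pz) - dot * dot
                    if perp2 > rmax2:
                        rmax2 = perp2
                rmax = np.sqrt(rmax2)
                nsub = 1
                if rmax > 0.0:
                    arg = 0.999 * r / (2.0 * rmax)
                    if arg < 1.0:
                        dth = 2.0 * np.arcsin(arg)
                        nsub = int(np.ceil(abs(theta) / dth))
                        if nsub < 1:
                            nsub = 1
                restrict = 1 if sweep_other == 0 else 0
                for k in range(1, nsub):
                    ck = np.cos(theta * k / nsub)
                    sk = np.sin(theta * k / nsub)
                    for t in range(nm):
                        b = moved[t]
                        px, py, pz = _rotate_one(pos[b, 0], pos[b, 1],
                                                 pos[b, 2], ax, ay, az,
                                                 ux, uy, uz, ck, sk)
                        if _collides(px, py, pz, b, restrict, c, start1,
                                     n0, n1, circ0, circ1, pos, moved_flag,
                                     rr2, x0, z0, inv_e, ncx, ncy, ncz,
                                     head, nxt):
                            ok = False
                            break
                    if not ok:
                        break

            for t in range(nm):
                moved_flag[moved[t]] = 0

        if ok:
            for t in range(nm):
                b = moved[t]
                _cells_update(b, newpos[t, 0], newpos[t, 1], newpos[t, 2],
                              x0, z0, inv_e, ncx, ncy, ncz,
                              head, nxt, cell_of)
                pos[b, 0] = newpos[t, 0]
                pos[b, 1] = newpos[t, 1]
                pos[b, 2] = newpos[t, 2]
            accepted += 1

    return accepted
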