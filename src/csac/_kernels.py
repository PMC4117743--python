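"""Compiled hot loops for chain growth and candidate evaluation.

The grower maintains an open-addressing spatial hash of occupied bead
positions (cell edge = 4 bead diameters).  At every growth step the beads
within ``L_p + d_f`` of the chain end are gathered once; each of the ``k``
candidate directions is then tested against that local neighbourhood.  For
a neighbour bead ``y`` and a candidate unit along ``u``, the interpolated
bead nearest to ``y`` is at index ``j* = clamp(round(<y - x_t, u>/d_f))``;
since the squared distance is convex in the bead index, checking ``j*``
alone decides overlap exactly.  Tests assert equivalence with a brute-force
all-pairs oracle, so the acceleration is observationally invisible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by grow_chain_kernel
COMPLETED = 0
DEAD_END = 1

_KEY_OFF = 1 << 20
_KEY_MASK = (1 << 21) - 1


@njit(cache=True, fastmath=False)
def _hash_slot(key, mask):
    h = (key * np.int64(-7046029254386353131)) & np.int64(0x7FFFFFFFFFFFFFFF)
    return h & mask


@njit(cache=True)
def grow_chain_kernel(n_units, bpu, seg, dirs, r_allow, seed, rotate, tol):
    """Grow one chain of ``n_units`` persistence units.

    Parameters are scalars plus ``dirs`` (k, 3) unit candidate directions.
    ``r_allow`` is the maximum bead-centre radius (np.inf = unconfined).
    Returns ``(status, coords, log_weight, steps_completed, m_counts)``.
    """
    np.random.seed(seed)
    k = dirs.shape[0]
    d2 = np.empty_like(dirs)
    if rotate:
        # uniform random rotation from a normalized quaternion
        qw = np.random.normal()
        qx = np.random.normal()
        qy = np.random.normal()
        qz = np.random.normal()
        qn = np.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
        qw /= qn; qx /= qn; qy /= qn; qz /= qn
        r00 = 1 - 2 * (qy * qy + qz * qz)
        r01 = 2 * (qx * qy - qz * qw)
        r02 = 2 * (qx * qz + qy * qw)
        r10 = 2 * (qx * qy + qz * qw)
        r11 = 1 - 2 * (qx * qx + qz * qz)
        r12 = 2 * (qy * qz - qx * qw)
        r20 = 2 * (qx * qz - qy * qw)
        r21 = 2 * (qy * qz + qx * qw)
        r22 = 1 - 2 * (qx * qx + qy * qy)
        for c in range(k):
            ax, ay, az = dirs[c, 0], dirs[c, 1], dirs[c, 2]
            d2[c, 0] = r00 * ax + r01 * ay + r02 * az
            d2[c, 1] = r10 * ax + r11 * ay + r12 * az
            d2[c, 2] = r20 * ax + r21 * ay + r22 * az
    else:
        d2[:] = dirs

    lp = bpu * seg
    n_beads = n_units + (n_units - 1) * (bpu - 1)
    coords = np.empty((n_beads, 3))
    m_counts = np.zeros(max(n_units - 1, 1), np.int64)

    # spatial hash: open addressing, chained bead lists per cell
    cell = 4.0 * seg
    reach = int(np.ceil((bpu + 1) * seg / cell))
    size = 64
    while size < 4 * n_beads:
        size <<= 1
    mask = np.int64(size - 1)
    h_key = np.full(size, np.int64(-1))
    h_head = np.full(size, np.int64(-1))
    nxt = np.full(n_beads, np.int64(-1))

    # seed bead: uniform in the allowed sphere when confined, origin otherwise
    x0 = np.zeros(3)
    if np.isfinite(r_allow):
        while True:
            x0[0] = (2.0 * np.random.random() - 1.0) * r_allow
            x0[1] = (2.0 * np.random.random() - 1.0) * r_allow
            x0[2] = (2.0 * np.random.random() - 1.0) * r_allow
            if x0[0] ** 2 + x0[1] ** 2 + x0[2] ** 2 <= r_allow * r_allow:
                break
    coords[0, 0] = x0[0]
    coords[0, 1] = x0[1]
    coords[0, 2] = x0[2]

    # insert bead 0
    ix = np.int64(np.floor(coords[0, 0] / cell)) + _KEY_OFF
    iy = np.int64(np.floor(coords[0, 1] / cell)) + _KEY_OFF
    iz = np.int64(np.floor(coords[0, 2] / cell)) + _KEY_OFF
    key = (ix << 42) | (iy << 21) | iz
    s = _hash_slot(key, mask)
    while h_key[s] != -1 and h_key[s] != key:
        s = (s + 1) & mask
    h_key[s] = key
    nxt[0] = h_head[s]
    h_head[s] = 0

    n_placed = 1
    xtx, xty, xtz = coords[0, 0], coords[0, 1], coords[0, 2]
    feas = np.empty(k, np.int64)
    nb = np.empty((n_beads, 3))
    log_w = 0.0
    gather_r2 = ((bpu + 1) * seg) ** 2
    viol2 = (seg - tol) ** 2
    r_allow2 = r_allow * r_allow if np.isfinite(r_allow) else 0.0
    confined = np.isfinite(r_allow)

    for t in range(n_units - 1):
        # gather occupied beads near the chain end
        n_nb = 0
        cx = np.int64(np.floor(xtx / cell))
        cy = np.int64(np.floor(xty / cell))
        cz = np.int64(np.floor(xtz / cell))
        for ox in range(-reach, reach + 1):
            gx = cx + ox + _KEY_OFF
            for oy in range(-reach, reach + 1):
                gy = cy + oy + _KEY_OFF
                for oz in range(-reach, reach + 1):
                    gz = cz + oz + _KEY_OFF
                    key = (gx << 42) | (gy << 21) | gz
                    s = _hash_slot(key, mask)
                    while h_key[s] != -1:
                        if h_key[s] == key:
                            b = h_head[s]
                            while b != -1:
                                dx = coords[b, 0] - xtx
                                dy = coords[b, 1] - xty
                                dz = coords[b, 2] - xtz
                                if dx * dx + dy * dy + dz * dz <= gather_r2:
                                    nb[n_nb, 0] = dx
                                    nb[n_nb, 1] = dy
                                    nb[n_nb, 2] = dz
                                    n_nb += 1
                                b = nxt[b]
                            break
                        s = (s + 1) & mask

        # evaluate candidate directions
        m = 0
        for c in range(k):
            ux, uy, uz = d2[c, 0], d2[c, 1], d2[c, 2]
            if confined:
                ex = xtx + lp * ux
                ey = xty + lp * uy
                ez = xtz + lp * uz
                # the sphere is convex and x_t is inside, so checking the
                # unit endpoint covers all interpolated beads
                if ex * ex + ey * ey + ez * ez > r_allow2:
                    continue
            ok = True
            for i in range(n_nb):
                dx, dy, dz = nb[i, 0], nb[i, 1], nb[i, 2]
                proj = dx * ux + dy * uy + dz * uz
                j = np.int64(np.floor(proj / seg + 0.5))
                if j < 1:
                    j = 1
                elif j > bpu:
                    j = bpu
                pj = j * seg
                vx = dx - pj * ux
                vy = dy - pj * uy
                vz = dz - pj * uz
                if vx * vx + vy * vy + vz * vz < viol2:
                    ok = False
                    break
            if ok:
                feas[m] = c
                m += 1

        m_counts[t] = m
        if m == 0:
            return DEAD_END, coords, log_w, t, m_counts
        log_w += np.log(m / k)
        pick = np.int64(np.random.random() * m)
        if pick >= m:
            pick = m - 1
        c = feas[pick]
        ux, uy, uz = d2[c, 0], d2[c, 1], d2[c, 2]
        for j in range(1, bpu + 1):
            b = n_placed + j - 1
            coords[b, 0] = xtx + j * seg * ux
            coords[b, 1] = xty + j * seg * uy
            coords[b, 2] = xtz + j * seg * uz
            ix = np.int64(np.floor(coords[b, 0] / cell)) + _KEY_OFF
            iy = np.int64(np.floor(coords[b, 1] / cell)) + _KEY_OFF
            iz = np.int64(np.floor(coords[b, 2] / cell)) + _KEY_OFF
            key = (ix << 42) | (iy << 21) | iz
            s = _hash_slot(key, mask)
            while h_key[s] != -1 and h_key[s] != key:
                s = (s + 1) & mask
            h_key[s] = key
            nxt[b] = h_head[s]
            h_head[s] = b
        n_placed += bpu
        xtx = coords[n_placed - 1, 0]
        xty = coords[n_placed - 1, 1]
        xtz = coords[n_placed - 1, 2]

    return COMPLETED, coords, log_w, n_units - 1, m_counts


@njit(cache=True)
def extend_chain_kernel(coords, n_placed, n_grow_units, bpu, seg, dirs,
                        r_allow, seed, rotate, tol):
    """Extend a partial chain in place by up to ``n_grow_units`` units.

    ``coords`` is the preallocated (N'_total, 3) array whose first
    ``n_placed`` rows are already-placed beads (``n_placed == 0`` places
    the seed bead first).  Semantics are identical to
    ``grow_chain_kernel``; the spatial hash is rebuilt from the existing
    beads on entry.  Returns ``(status, new_n_placed, log_weight_increment,
    steps_done)``.
    """
    np.random.seed(seed)
    k = dirs.shape[0]
    d2 = np.empty_like(dirs)
    if rotate:
        qw = np.random.normal()
        qx = np.random.normal()
        qy = np.random.normal()
        qz = np.random.normal()
        qn = np.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
        qw /= qn; qx /= qn; qy /= qn; qz /= qn
        r00 = 1 - 2 * (qy * qy + qz * qz)
        r01 = 2 * (qx * qy - qz * qw)
        r02 = 2 * (qx * qz + qy * qw)
        r10 = 2 * (qx * qy + qz * qw)
        r11 = 1 - 2 * (qx * qx + qz * qz)
        r12 = 2 * (qy * qz - qx * qw)
        r20 = 2 * (qx * qz - qy * qw)
        r21 = 2 * (qy * qz + qx * qw)
        r22 = 1 - 2 * (qx * qx + qy * qy)
        for c in range(k):
            ax, ay, az = dirs[c, 0], dirs[c, 1], dirs[c, 2]
            d2[c, 0] = r00 * ax + r01 * ay + r02 * az
            d2[c, 1] = r10 * ax + r11 * ay + r12 * az
            d2[c, 2] = r20 * ax + r21 * ay + r22 * az
    else:
        d2[:] = dirs

    lp = bpu * seg
    n_beads = coords.shape[0]
    cell = 4.0 * seg
    reach = int(np.ceil((bpu + 1) * seg / cell))
    size = 64
    while size < 4 * n_beads:
        size <<= 1
    mask = np.int64(size - 1)
    h_key = np.full(size, np.int64(-1))
    h_head = np.full(size, np.int64(-1))
    nxt = np.full(n_beads, np.int64(-1))

    if n_placed == 0:
        x0 = np.zeros(3)
        if np.isfinite(r_allow):
            while True:
                x0[0] = (2.0 * np.random.random() - 1.0) * r_allow
                x0[1] = (2.0 * np.random.random() - 1.0) * r_allow
                x0[2] = (2.0 * np.random.random() - 1.0) * r_allow
                if x0[0] ** 2 + x0[1] ** 2 + x0[2] ** 2 <= r_allow * r_allow:
                    break
        coords[0, 0] = x0[0]
        coords[0, 1] = x0[1]
        coords[0, 2] = x0[2]
        n_placed = 1

    # rebuild the spatial hash from the existing beads
    for b in range(n_placed):
        ix = np.int64(np.floor(coords[b, 0] / cell)) + _KEY_OFF
        iy = np.int64(np.floor(coords[b, 1] / cell)) + _KEY_OFF
        iz = np.int64(np.floor(coords[b, 2] / cell)) + _KEY_OFF
        key = (ix << 42) | (iy << 21) | iz
        s = _hash_slot(key, mask)
        while h_key[s] != -1 and h_key[s] != key:
            s = (s + 1) & mask
        h_key[s] = key
        nxt[b] = h_head[s]
        h_head[s] = b

    xtx, xty, xtz = coords[n_placed - 1, 0], coords[n_placed - 1, 1], coords[n_placed - 1, 2]
    feas = np.empty(k, np.int64)
    nb = np.empty((n_beads, 3))
    log_w = 0.0
    gather_r2 = ((bpu + 1) * seg) ** 2
    viol2 = (seg - tol) ** 2
    confined = np.isfinite(r_allow)
    r_allow2 = r_allow * r_allow if confined else 0.0

    steps = 0
    for t in range(n_grow_units):
        if n_placed + bpu > n_beads:
            break
        n_nb = 0
        cx = np.int64(np.floor(xtx / cell))
        cy = np.int64(np.floor(xty / cell))
        cz = np.int64(np.floor(xtz / cell))
        for ox in range(-reach, reach + 1):
            gx = cx + ox + _KEY_OFF
            for oy in range(-reach, reach + 1):
                gy = cy + oy + _KEY_OFF
                for oz in range(-reach, reach + 1):
                    gz = cz + oz + _KEY_OFF
                    key = (gx << 42) | (gy << 21) | gz
                    s = _hash_slot(key, mask)
                    while h_key[s] != -1:
                        if h_key[s] == key:
                            b = h_head[s]
                            while b != -1:
                                dx = coords[b, 0] - xtx
                                dy = coords[b, 1] - xty
                                dz = coords[b, 2] - xtz
                                if dx * dx + dy * dy + dz * dz <= gather_r2:
                                    nb[n_nb, 0] = dx
                                    nb[n_nb, 1] = dy
                                    nb[n_nb, 2] = dz
                                    n_nb += 1
                                b = nxt[b]
                            break
                        s = (s + 1) & mask
        m = 0
        for c in range(k):
            ux, uy, uz = d2[c, 0], d2[c, 1], d2[c, 2]
            if confined:
                ex = xtx + lp * ux
                ey = xty + lp * uy
                ez = xtz + lp * uz
                if ex * ex + ey * ey + ez * ez > r_allow2:
                    continue
            ok = True
            for i in range(n_nb):
                dx, dy, dz = nb[i, 0], nb[i, 1], nb[i, 2]
                proj = dx * ux + dy * uy + dz * uz
                j = np.int64(np.floor(proj / seg + 0.5))
                if j < 1:
                    j = 1
                elif j > bpu:
                    j = bpu
                pj = j * seg
                vx = dx - pj * ux
                vy = dy - pj * uy
                vz = dz - pj * uz
                if vx * vx + vy * vy + vz * vz < viol2:
                    ok = False
                    break
            if ok:
                feas[m] = c
                m += 1
        if m == 0:
            return DEAD_END, n_placed, log_w, steps
        log_w += np.log(m / k)
        pick = np.int64(np.random.random() * m)
        if pick >= m:
            pick = m - 1
        c = feas[pick]
        ux, uy, uz = d2[c, 0], d2[c, 1], d2[c, 2]
        for j in range(1, bpu + 1):
            b = n_placed + j - 1
            coords[b, 0] = xtx + j * seg * ux
            coords[b, 1] = xty + j * seg * uy
            coords[b, 2] = xtz + j * seg * uz
            ix = np.int64(np.floor(coords[b, 0] / cell)) + _KEY_OFF
            iy = np.int64(np.floor(coords[b, 1] / cell)) + _KEY_OFF
            iz = np.int64(np.floor(coords[b, 2] / cell)) + _KEY_OFF
            key = (ix << 42) | (iy << 21) | iz
            s = _hash_slot(key, mask)
            while h_key[s] != -1 and h_key[s] != key:
                s = (s + 1) & mask
            h_key[s] = key
            nxt[b] = h_head[s]
            h_head[s] = b
        n_placed += bpu
        xtx = coords[n_placed - 1, 0]
        xty = coords[n_placed - 1, 1]
        xtz = coords[n_placed - 1, 2]
        steps += 1

    return COMPLETED, n_placed, log_w, steps


@njit(cache=True)
def feasible_mask_kernel(existing, end, dirs, r_allow, seg, bpu, tol):
    """Boolean feasibility of each candidate direction for the next unit.

    ``existing`` is the (n, 3) array of already-placed beads, ``end`` the
    current chain end (a row of ``existing``).  Semantics match one step of
    ``grow_chain_kernel`` exactly.
    """
    k = dirs.shape[0]
    n = existing.shape[0]
    lp = bpu * seg
    out = np.ones(k, np.bool_)
    gather_r2 = ((bpu + 1) * seg) ** 2
    viol2 = (seg - tol) ** 2
    confined = np.isfinite(r_allow)
    r_allow2 = r_allow * r_allow if confined else 0.0

    # prefilter beads that can possibly conflict
    nb = np.empty((n, 3))
    n_nb = 0
    for i in range(n):
        dx = existing[i, 0] - end[0]
        dy = existing[i, 1] - end[1]
        dz = existing[i, 2] - end[2]
        if dx * dx + dy * dy + dz * dz <= gather_r2:
            nb[n_nb, 0] = dx
            nb[n_nb, 1] = dy
            nb[n_nb, 2] = dz
            n_nb += 1

    for c in range(k):
        ux, uy, uz = dirs[c, 0], dirs[c, 1], dirs[c, 2]
        if confined:
            ex = end[0] + lp * ux
            ey = end[1] + lp * uy
            ez = end[2] + lp * uz
            if ex * ex + ey * ey + ez * ez > r_allow2:
                out[c] = False
                continue
        for i in range(n_nb):
            dx, dy, dz = nb[i, 0], nb[i, 1], nb[i, 2]
            proj = dx * ux + dy * uy + dz * uz
            j = np.int64(np.floor(proj / seg + 0.5))
            if j < 1:
                j = 1
            elif j > bpu:
                j = bpu
            pj = j * seg
            vx = dx - pj * ux
            vy = dy - pj * uy
            vz = dz - pj * uz
            if vx * vx + vy * vy + vz * vz < viol2:
                out[c] = False
                break
    return out
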