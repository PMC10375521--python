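"""Numba-jitted numerical kernels.

Everything here works on plain float64/int64 arrays so the hot paths (Metropolis
sweeps, pair histograms, overlap tests) stay allocation-light and jit-friendly.
The public modules wrap these in typed dataclasses.

Conventions: lengths in nm, energies in units of the well depth u0 (a stacking
bond contributes -1), cubic periodic box of edge ``box``.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# basic vector helpers
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _min_image(dx, dy, dz, box):
    dx -= box * np.round(dx / box)
    dy -= box * np.round(dy / box)
    dz -= box * np.round(dz / box)
    return dx, dy, dz


@njit(cache=True, fastmath=True)
def _rotate_about(v, u, c, s):
    """Rodrigues rotation of vector v about unit axis u (cos c, sin s)."""
    ux, uy, uz = u[0], u[1], u[2]
    vx, vy, vz = v[0], v[1], v[2]
    dot = ux * vx + uy * vy + uz * vz
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    out = np.empty(3)
    out[0] = vx * c + cx * s + ux * dot * (1.0 - c)
    out[1] = vy * c + cy * s + uy * dot * (1.0 - c)
    out[2] = vz * c + cz * s + uz * dot * (1.0 - c)
    return out


# ---------------------------------------------------------------------------
# GJK overlap test for two finite flat-capped cylinders (convex bodies)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _support_cyl(px, py, pz, ax, ay, az, hL, R, dx, dy, dz):
    """Farthest point of a cylinder (center p, unit axis a, half-length hL,
    radius R) in direction d."""
    ad = dx * ax + dy * ay + dz * az
    qx = dx - ad * ax
    qy = dy - ad * ay
    qz = dz - ad * az
    qn = np.sqrt(qx * qx + qy * qy + qz * qz)
    s = hL if ad >= 0.0 else -hL
    ox = px + s * ax
    oy = py + s * ay
    oz = pz + s * az
    if qn > 1e-14:
        f = R / qn
        ox += f * qx
        oy += f * qy
        oz += f * qz
    return ox, oy, oz


@njit(cache=True, fastmath=True)
def gjk_cylinders_overlap(pa, aa, hLa, Ra, pb, ab, hLb, Rb):
    """True iff the two closed cylinders intersect (GJK boolean query).

    A separation smaller than ~1e-10 of the body scale may be classified either
    way; the caller treats exact touching as non-overlapping.
    """
    # simplex storage (up to 4 points of the Minkowski difference A - B)
    sim = np.empty((4, 3))
    nsim = 0
    dx = pb[0] - pa[0]
    dy = pb[1] - pa[1]
    dz = pb[2] - pa[2]
    if dx * dx + dy * dy + dz * dz < 1e-24:
        dx = 1.0
    scale = hLa + Ra + hLb + Rb
    tol = 1e-12 * scale * scale

    for _ in range(200):
        # support of Minkowski difference in direction d
        sax, say, saz = _support_cyl(pa[0], pa[1], pa[2], aa[0], aa[1], aa[2],
                                     hLa, Ra, dx, dy, dz)
        sbx, sby, sbz = _support_cyl(pb[0], pb[1], pb[2], ab[0], ab[1], ab[2],
                                     hLb, Rb, -dx, -dy, -dz)
        wx = sax - sbx
        wy = say - sby
        wz = saz - sbz
        if wx * dx + wy * dy + wz * dz < tol:
            return False  # new point does not pass the origin: separated
        sim[nsim, 0] = wx
        sim[nsim, 1] = wy
        sim[nsim, 2] = wz
        nsim += 1

        # ---- do-simplex: update simplex and search direction ----
        if nsim == 1:
            dx, dy, dz = -sim[0, 0], -sim[0, 1], -sim[0, 2]
        elif nsim == 2:
            # segment AB, A = last inserted
            ax_ = sim[1, 0]
            ay_ = sim[1, 1]
            az_ = sim[1, 2]
            abx = sim[0, 0] - ax_
            aby = sim[0, 1] - ay_
            abz = sim[0, 2] - az_
            aox, aoy, aoz = -ax_, -ay_, -az_
            if abx * aox + aby * aoy + abz * aoz > 0.0:
                # d = AB x AO x AB
                cx = aby * aoz - abz * aoy
                cy = abz * aox - abx * aoz
                cz = abx * aoy - aby * aox
                dx = cy * abz - cz * aby
                dy = cz * abx - cx * abz
                dz = cx * aby - cy * abx
                if dx * dx + dy * dy + dz * dz < 1e-30:
                    # origin on the segment line
                    return True
            else:
                sim[0] = sim[1]
                nsim = 1
                dx, dy, dz = aox, aoy, aoz
        elif nsim == 3:
            keep, dx, dy, dz, hit = _triangle_case(sim)
            if hit:
                return True
            nsim = keep
        else:
            keep, dx, dy, dz, hit = _tetra_case(sim)
            if hit:
                return True
            nsim = keep
    return True  # no convergence: treat as overlapping (conservative for MC)


@njit(cache=True, fastmath=True)
def _triangle_case(sim):
    """Triangle simplex [B, C, A] with A = sim[2] the newest point."""
    A = sim[2]
    B = sim[0]
    C = sim[1]
    abx, aby, abz = B[0] - A[0], B[1] - A[1], B[2] - A[2]
    acx, acy, acz = C[0] - A[0], C[1] - A[1], C[2] - A[2]
    aox, aoy, aoz = -A[0], -A[1], -A[2]
    nx = aby * acz - abz * acy
    ny = abz * acx - abx * acz
    nz = abx * acy - aby * acx
    # edge AC region?
    px = ny * acz - nz * acy  # n x AC ... actually (n x AC)
    py = nz * acx - nx * acz
    pz = nx * acy - ny * acx
    if px * aox + py * aoy + pz * aoz > 0.0:
        if acx * aox + acy * aoy + acz * aoz > 0.0:
            sim[0] = C
            sim[1] = A
            # d = AC x AO x AC
            cx = acy * aoz - acz * aoy
            cy = acz * aox - acx * aoz
            cz = acx * aoy - acy * aox
            dx = cy * acz - cz * acy
            dy = cz * acx - cx * acz
            dz = cx * acy - cy * acx
            return 2, dx, dy, dz, False
        # fall through to AB check
        if abx * aox + aby * aoy + abz * aoz > 0.0:
            sim[0] = B
            sim[1] = A
            cx = aby * aoz - abz * aoy
            cy = abz * aox - abx * aoz
            cz = abx * aoy - aby * aox
            dx = cy * abz - cz * aby
            dy = cz * abx - cx * abz
            dz = cx * aby - cy * abx
            return 2, dx, dy, dz, False
        sim[0] = A
        return 1, aox, aoy, aoz, False
    qx = aby * nz - abz * ny  # AB x n
    qy = abz * nx - abx * nz
    qz = abx * ny - aby * nx
    if qx * aox + qy * aoy + qz * aoz > 0.0:
        if abx * aox + aby * aoy + abz * aoz > 0.0:
            sim[0] = B
            sim[1] = A
            cx = aby * aoz - abz * aoy
            cy = abz * aox - abx * aoz
            cz = abx * aoy - aby * aox
            dx = cy * abz - cz * aby
            dy = cz * abx - cx * abz
            dz = cx * aby - cy * abx
            return 2, dx, dy, dz, False
        sim[0] = A
        return 1, aox, aoy, aoz, False
    # origin above or below the triangle plane
    d = nx * aox + ny * aoy + nz * aoz
    if d > 0.0:
        # keep [B, C, A], search along n
        return 3, nx, ny, nz, False
    # swap winding: [C, B, A], search along -n
    tmp0, tmp1, tmp2 = B[0], B[1], B[2]
    sim[0, 0], sim[0, 1], sim[0, 2] = C[0], C[1], C[2]
    sim[1, 0], sim[1, 1], sim[1, 2] = tmp0, tmp1, tmp2
    return 3, -nx, -ny, -nz, False


@njit(cache=True, fastmath=True)
def _tetra_case(sim):
    """Tetrahedron [B, C, D, A] with A = sim[3] newest; origin containment."""
    A = sim[3]
    B = sim[0]
    C = sim[1]
    D = sim[2]
    aox, aoy, aoz = -A[0], -A[1], -A[2]
    abx, aby, abz = B[0] - A[0], B[1] - A[1], B[2] - A[2]
    acx, acy, acz = C[0] - A[0], C[1] - A[1], C[2] - A[2]
    adx, ady, adz = D[0] - A[0], D[1] - A[1], D[2] - A[2]

    # face ABC (normal oriented away from D)
    n1x = aby * acz - abz * acy
    n1y = abz * acx - abx * acz
    n1z = abx * acy - aby * acx
    if n1x * adx + n1y * ady + n1z * adz > 0.0:
        n1x, n1y, n1z = -n1x, -n1y, -n1z
    # face ACD (away from B)
    n2x = acy * adz - acz * ady
    n2y = acz * adx - acx * adz
    n2z = acx * ady - acy * adx
    if n2x * abx + n2y * aby + n2z * abz > 0.0:
        n2x, n2y, n2z = -n2x, -n2y, -n2z
    # face ADB (away from C)
    n3x = ady * abz - adz * aby
    n3y = adz * abx - adx * abz
    n3z = adx * aby - ady * abx
    if n3x * acx + n3y * acy + n3z * acz > 0.0:
        n3x, n3y, n3z = -n3x, -n3y, -n3z

    if n1x * aox + n1y * aoy + n1z * aoz > 0.0:
        sim[2] = A  # simplex [B, C, A]
        return _triangle_case(sim)
    if n2x * aox + n2y * aoy + n2z * aoz > 0.0:
        sim[0] = C
        sim[1] = D
        sim[2] = A
        return _triangle_case(sim)
    if n3x * aox + n3y * aoy + n3z * aoz > 0.0:
        sim[1] = B
        sim[0] = D
        sim[2] = A
        return _triangle_case(sim)
    return 4, 0.0, 0.0, 0.0, True  # origin inside all faces


@njit(cache=True, fastmath=True)
def overlap_mi(pos, ax, i, j, hL, R, box):
    """Min-image overlap between particles i and j of one configuration."""
    dxx, dyy, dzz = _min_image(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                               pos[j, 2] - pos[i, 2], box)
    rc2 = hL * hL + R * R
    if dxx * dxx + dyy * dyy + dzz * dzz >= 4.0 * rc2:
        return False
    pb = np.empty(3)
    pb[0] = pos[i, 0] + dxx
    pb[1] = pos[i, 1] + dyy
    pb[2] = pos[i, 2] + dzz
    return gjk_cylinders_overlap(pos[i], ax[i], hL, R, pb, ax[j], hL, R)


# ---------------------------------------------------------------------------
# square-well stacking energy
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _pair_bonds(pix, piy, piz, aix, aiy, aiz, spi, smi,
                pjx, pjy, pjz, ajx, ajy, ajz, spj, smj,
                site_off, delta2, box):
    """Number of stacking site pairs of particles i, j within the well.

    sp*/sm* flag the existence of the +axis / -axis site. Strict inequality:
    r = delta is outside the well.
    """
    nb = 0
    for si in range(2):
        if si == 0:
            if not spi:
                continue
            ox, oy, oz = site_off * aix, site_off * aiy, site_off * aiz
        else:
            if not smi:
                continue
            ox, oy, oz = -site_off * aix, -site_off * aiy, -site_off * aiz
        six = pix + ox
        siy = piy + oy
        siz = piz + oz
        for sj in range(2):
            if sj == 0:
                if not spj:
                    continue
                qx, qy, qz = site_off * ajx, site_off * ajy, site_off * ajz
            else:
                if not smj:
                    continue
                qx, qy, qz = -site_off * ajx, -site_off * ajy, -site_off * ajz
            dx, dy, dz = _min_image(pjx + qx - six, pjy + qy - siy,
                                    pjz + qz - siz, box)
            if dx * dx + dy * dy + dz * dz < delta2:
                nb += 1
    return nb


@njit(cache=True)
def total_energy(pos, ax, sp, sm, site_off, delta, box):
    """All-pairs SW energy in units of u0 (each bond contributes -1)."""
    n = pos.shape[0]
    d2 = delta * delta
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            e -= _pair_bonds(pos[i, 0], pos[i, 1], pos[i, 2],
                             ax[i, 0], ax[i, 1], ax[i, 2], sp[i], sm[i],
                             pos[j, 0], pos[j, 1], pos[j, 2],
                             ax[j, 0], ax[j, 1], ax[j, 2], sp[j], sm[j],
                             site_off, d2, box)
    return e


@njit(cache=True)
def any_overlap(pos, ax, hL, R, box):
    n = pos.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if overlap_mi(pos, ax, i, j, hL, R, box):
                return True
    return False


@njit(cache=True)
def bond_edges(pos, ax, sp, sm, site_off, delta, box):
    """All-pairs bonded edge list (m, 2) of particle indices."""
    n = pos.shape[0]
    d2 = delta * delta
    out = np.empty((n * 2, 2), dtype=np.int64)
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            nb = _pair_bonds(pos[i, 0], pos[i, 1], pos[i, 2],
                             ax[i, 0], ax[i, 1], ax[i, 2], sp[i], sm[i],
                             pos[j, 0], pos[j, 1], pos[j, 2],
                             ax[j, 0], ax[j, 1], ax[j, 2], sp[j], sm[j],
                             site_off, d2, box)
            if nb > 0:
                if m >= out.shape[0]:
                    grown = np.empty((out.shape[0] * 2, 2), dtype=np.int64)
                    grown[:m] = out[:m]
                    out = grown
                out[m, 0] = i
                out[m, 1] = j
                m += 1
    return out[:m].copy()


# ---------------------------------------------------------------------------
# cell list
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _cell_index(x, y, z, box, nc):
    cx = int(x / box * nc) % nc
    cy = int(y / box * nc) % nc
    cz = int(z / box * nc) % nc
    return (cx * nc + cy) * nc + cz


@njit(cache=True)
def _build_cells(pos, box, nc, head, nxt, prv, cell_of):
    head[:] = -1
    n = pos.shape[0]
    for i in range(n):
        c = _cell_index(pos[i, 0], pos[i, 1], pos[i, 2], box, nc)
        cell_of[i] = c
        nxt[i] = head[c]
        prv[i] = -1
        if head[c] >= 0:
            prv[head[c]] = i
        head[c] = i


@njit(cache=True)
def _relocate(i, newcell, head, nxt, prv, cell_of):
    old = cell_of[i]
    if old == newcell:
        return
    # unlink
    if prv[i] >= 0:
        nxt[prv[i]] = nxt[i]
    else:
        head[old] = nxt[i]
    if nxt[i] >= 0:
        prv[nxt[i]] = prv[i]
    # insert
    cell_of[i] = newcell
    nxt[i] = head[newcell]
    prv[i] = -1
    if head[newcell] >= 0:
        prv[head[newcell]] = i
    head[newcell] = i


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo driver
# ---------------------------------------------------------------------------


@njit(cache=True)
def _local_interactions(i, px, py, pz, axx, axy, axz, pos, ax, sp, sm,
                        hL, R, site_off, delta2, box, nc, head, nxt,
                        check_overlap):
    """(overlap, energy) of a candidate configuration of particle i against all
    neighbors found through the cell list around point p."""
    e = 0.0
    cx = int(px / box * nc) % nc
    cy = int(py / box * nc) % nc
    cz = int(pz / box * nc) % nc
    rc2 = 4.0 * (hL * hL + R * R)
    cand = np.empty(3)
    axis_i = np.empty(3)
    axis_i[0] = axx
    axis_i[1] = axy
    axis_i[2] = axz
    # with fewer than 3 cells per dimension the +-1 neighborhood would visit
    # a cell twice, double counting pairs; restrict the stencil instead
    lo, hi = (-1, 2) if nc >= 3 else ((0, 1) if nc == 1 else (0, 2))
    for ox in range(lo, hi):
        gx = (cx + ox) % nc
        for oy in range(lo, hi):
            gy = (cy + oy) % nc
            for oz in range(lo, hi):
                gz = (cz + oz) % nc
                j = head[(gx * nc + gy) * nc + gz]
                while j >= 0:
                    if j != i:
                        dxx, dyy, dzz = _min_image(
                            pos[j, 0] - px, pos[j, 1] - py, pos[j, 2] - pz, box)
                        r2 = dxx * dxx + dyy * dyy + dzz * dzz
                        if check_overlap and r2 < rc2:
                            cand[0] = px + dxx
                            cand[1] = py + dyy
                            cand[2] = pz + dzz
                            here = np.empty(3)
                            here[0] = px
                            here[1] = py
                            here[2] = pz
                            if gjk_cylinders_overlap(here, axis_i, hL, R,
                                                     cand, ax[j], hL, R):
                                return True, 0.0
                        e -= _pair_bonds(px, py, pz, axx, axy, axz,
                                         sp[i], sm[i],
                                         pos[j, 0], pos[j, 1], pos[j, 2],
                                         ax[j, 0], ax[j, 1], ax[j, 2],
                                         sp[j], sm[j], site_off, delta2, box)
                    j = nxt[j]
    return False, e


@njit(cache=True, fastmath=True)
def _tether_ok(i, px, py, pz, axx, axy, axz, upx, upy, upz,
               pos, ax, up, cov_next, cov_prev, hL, rimR, dcov2, box):
    """Covalent rim-site constraints of particle i at a candidate pose."""
    jn = cov_next[i]
    if jn >= 0:
        # my +rim vs partner's -rim
        sx = px + hL * axx + rimR * upx
        sy = py + hL * axy + rimR * upy
        sz = pz + hL * axz + rimR * upz
        tx = pos[jn, 0] - hL * ax[jn, 0] + rimR * up[jn, 0]
        ty = pos[jn, 1] - hL * ax[jn, 1] + rimR * up[jn, 1]
        tz = pos[jn, 2] - hL * ax[jn, 2] + rimR * up[jn, 2]
        dx, dy, dz = _min_image(tx - sx, ty - sy, tz - sz, box)
        if dx * dx + dy * dy + dz * dz > dcov2:
            return False
    jp = cov_prev[i]
    if jp >= 0:
        sx = px - hL * axx + rimR * upx
        sy = py - hL * axy + rimR * upy
        sz = pz - hL * axz + rimR * upz
        tx = pos[jp, 0] + hL * ax[jp, 0] + rimR * up[jp, 0]
        ty = pos[jp, 1] + hL * ax[jp, 1] + rimR * up[jp, 1]
        tz = pos[jp, 2] + hL * ax[jp, 2] + rimR * up[jp, 2]
        dx, dy, dz = _min_image(tx - sx, ty - sy, tz - sz, box)
        if dx * dx + dy * dy + dz * dz > dcov2:
            return False
    return True


@njit(cache=True)
def mc_run(pos, ax, up, sp, sm, cov_next, cov_prev,
           hL, R, site_off, rimR, delta, delta_cov, tstar, box,
           max_tr, max_rot, n_equil, n_prod, sample_every,
           seed, e0,
           pos_out, ax_out, up_out, e_trace):
    """Metropolis NVT sweeps; fills production snapshots and per-sweep energy.

    Returns (final_energy, n_acc_tr, n_att_tr, n_acc_rot, n_att_rot) with
    acceptance counted over the whole run. One sweep = N attempted single
    particle moves (50% translations, 50% rotations).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    d2 = delta * delta
    dcov2 = delta_cov * delta_cov
    has_cov = delta_cov > 0.0

    rc = 2.0 * np.sqrt(hL * hL + R * R) + delta
    nc = int(box / rc)
    if nc > 40:
        nc = 40
    use_cells = nc >= 3
    if not use_cells:
        nc = 1
    head = np.full(nc * nc * nc, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    prv = np.empty(n, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    _build_cells(pos, box, nc, head, nxt, prv, cell_of)

    etot = e0
    n_acc_tr = 0
    n_att_tr = 0
    n_acc_rot = 0
    n_att_rot = 0
    nsweeps = n_equil + n_prod
    isnap = 0
    axis_u = np.empty(3)

    for sweep in range(nsweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            translate = np.random.random() < 0.5
            if translate:
                n_att_tr += 1
                px = pos[i, 0] + (np.random.random() * 2.0 - 1.0) * max_tr
                py = pos[i, 1] + (np.random.random() * 2.0 - 1.0) * max_tr
                pz = pos[i, 2] + (np.random.random() * 2.0 - 1.0) * max_tr
                px -= box * np.floor(px / box)
                py -= box * np.floor(py / box)
                pz -= box * np.floor(pz / box)
                axx, axy, axz = ax[i, 0], ax[i, 1], ax[i, 2]
                upx, upy, upz = up[i, 0], up[i, 1], up[i, 2]
            else:
                n_att_rot += 1
                px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
                # random rotation axis
                ux = np.random.standard_normal()
                uy = np.random.standard_normal()
                uz = np.random.standard_normal()
                un = np.sqrt(ux * ux + uy * uy + uz * uz)
                if un < 1e-12:
                    ux, uy, uz, un = 1.0, 0.0, 0.0, 1.0
                axis_u[0] = ux / un
                axis_u[1] = uy / un
                axis_u[2] = uz / un
                ang = (np.random.random() * 2.0 - 1.0) * max_rot
                c = np.cos(ang)
                s = np.sin(ang)
                na = _rotate_about(ax[i], axis_u, c, s)
                nu = _rotate_about(up[i], axis_u, c, s)
                # re-unitize occasionally drifting vectors
                nn = np.sqrt(na[0] ** 2 + na[1] ** 2 + na[2] ** 2)
                na /= nn
                nn = np.sqrt(nu[0] ** 2 + nu[1] ** 2 + nu[2] ** 2)
                nu /= nn
                axx, axy, axz = na[0], na[1], na[2]
                upx, upy, upz = nu[0], nu[1], nu[2]

            if has_cov:
                if not _tether_ok(i, px, py, pz, axx, axy, axz,
                                  upx, upy, upz, pos, ax, up,
                                  cov_next, cov_prev, hL, rimR, dcov2, box):
                    continue

            # old local energy (no overlap check: current config is valid)
            _, e_old = _local_interactions(
                i, pos[i, 0], pos[i, 1], pos[i, 2],
                ax[i, 0], ax[i, 1], ax[i, 2], pos, ax, sp, sm,
                hL, R, site_off, d2, box, nc, head, nxt, False)
            ov, e_new = _local_interactions(
                i, px, py, pz, axx, axy, axz, pos, ax, sp, sm,
                hL, R, site_off, d2, box, nc, head, nxt, True)
            if ov:
                continue
            de = e_new - e_old
            if de > 0.0:
                if np.random.random() >= np.exp(-de / tstar):
                    continue
            # accept
            pos[i, 0], pos[i, 1], pos[i, 2] = px, py, pz
            ax[i, 0], ax[i, 1], ax[i, 2] = axx, axy, axz
            up[i, 0], up[i, 1], up[i, 2] = upx, upy, upz
            etot += de
            if translate:
                n_acc_tr += 1
                _relocate(i, _cell_index(px, py, pz, box, nc),
                          head, nxt, prv, cell_of)
            else:
                n_acc_rot += 1

        e_trace[sweep] = etot
        if sweep >= n_equil and (sweep - n_equil) % sample_every == 0:
            if isnap < pos_out.shape[0]:
                pos_out[isnap] = pos
                ax_out[isnap] = ax
                up_out[isnap] = up
                isnap += 1

    return etot, n_acc_tr, n_att_tr, n_acc_rot, n_att_rot


# ---------------------------------------------------------------------------
# pair-distance histograms (structure factor / Debye intensity)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def pair_distance_hist(pts, box, use_pbc, dr, nbins):
    """Histogram of pairwise distances (min image if use_pbc)."""
    n = pts.shape[0]
    h = np.zeros(nbins, dtype=np.int64)
    for i in range(n):
        xi, yi, zi = pts[i, 0], pts[i, 1], pts[i, 2]
        for j in range(i + 1, n):
            dx = pts[j, 0] - xi
            dy = pts[j, 1] - yi
            dz = pts[j, 2] - zi
            if use_pbc:
                dx, dy, dz = _min_image(dx, dy, dz, box)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            k = int(r / dr)
            if k < nbins:
                h[k] += 1
    return h


@njit(cache=True, fastmath=True)
def fill_cylinder_points(center, axis, upv, hL, R, npts, seed):
    """Uniform random points inside one finite cylinder (body frame spanned by
    axis, upv and their cross product)."""
    np.random.seed(seed)
    out = np.empty((npts, 3))
    wx = axis[1] * upv[2] - axis[2] * upv[1]
    wy = axis[2] * upv[0] - axis[0] * upv[2]
    wz = axis[0] * upv[1] - axis[1] * upv[0]
    for k in range(npts):
        while True:
            x = (np.random.random() * 2.0 - 1.0) * R
            y = (np.random.random() * 2.0 - 1.0) * R
            if x * x + y * y <= R * R:
                break
        z = (np.random.random() * 2.0 - 1.0) * hL
        out[k, 0] = center[0] + z * axis[0] + x * upv[0] + y * wx
        out[k, 1] = center[1] + z * axis[1] + x * upv[1] + y * wy
        out[k, 2] = center[2] + z * axis[2] + x * upv[2] + y * wz
    return out
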