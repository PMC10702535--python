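"""Numba-compiled sampling kernels.

All kernels operate on plain float64 arrays: molecule centers ``com``
(capacity, 3), per-molecule rotated bead offsets ``off`` (capacity, nb, 3)
and symmetric (nb, nb) bead-pair coefficient tables.  The minimum-image
convention is applied to center-of-mass separations and the same image
shift is used for all bead pairs of a molecule pair (molecules are small
compared to the box; the engine asserts this).

Energies are in kJ/mol.  A bead-pair separation of exactly zero returns
a large sentinel (1e100) which the acceptance step always rejects.
"""

import numpy as np
from numba import njit

BIG = 1e100


@njit(cache=True, inline="always")
def _min_image(dx, L):
    return dx - L * np.rint(dx / L)


@njit(cache=True)
def _pair_area(Ra, Rb, d):
    """Exposed area of two spheres at separation d (engulfed case
    clamped for continuity)."""
    big = Ra if Ra >= Rb else Rb
    small = Rb if Ra >= Rb else Ra
    full = 4.0 * np.pi * (big * big + small * small)
    if d >= big + small:
        return full
    if d <= big - small:
        return 4.0 * np.pi * big * big
    h_big = (small - big + d) * (small + big - d) / (2.0 * d)
    h_small = (big - small + d) * (big + small - d) / (2.0 * d)
    return full - 2.0 * np.pi * (big * h_big + small * h_small)


@njit(cache=True)
def mol_pair_energy(comA, offA, comB, offB, L,
                    sigma2, eps, coeff, contact, area0):
    """Interaction energy of two molecules (WCA + shifted SASA pair term)."""
    nb = offA.shape[0]
    dx = _min_image(comB[0] - comA[0], L)
    dy = _min_image(comB[1] - comA[1], L)
    dz = _min_image(comB[2] - comA[2], L)
    u = 0.0
    for a in range(nb):
        for b in range(nb):
            rx = dx + offB[b, 0] - offA[a, 0]
            ry = dy + offB[b, 1] - offA[a, 1]
            rz = dz + offB[b, 2] - offA[a, 2]
            r2 = rx * rx + ry * ry + rz * rz
            cab = contact[a, b]
            if r2 >= cab * cab:
                continue
            if r2 < 1e-12:
                return BIG
            r = np.sqrt(r2)
            # WCA (cutoff 2^(1/6) sigma always below contact here)
            s2 = sigma2[a, b] / r2
            if s2 > 0.7937005259840998:      # r < 2^(1/6) sigma
                s6 = s2 * s2 * s2
                u += 4.0 * eps[a, b] * (s6 * s6 - s6) + eps[a, b]
            # shifted SASA term
            u += coeff[a, b] * (_pair_area_ab(a, b, r, contact, area0)
                                - area0[a, b])
    return u


@njit(cache=True, inline="always")
def _pair_area_ab(a, b, d, contact, area0):
    """Exposed two-sphere area using tabulated contact and area sums."""
    # recover individual radii from contact = Ra+Rb and
    # area0 = 4*pi*(Ra^2+Rb^2)
    s = contact[a, b]
    q = area0[a, b] / (4.0 * np.pi)          # Ra^2 + Rb^2
    # Ra*Rb from (Ra+Rb)^2 - (Ra^2+Rb^2)
    p = 0.5 * (s * s - q)
    disc = 0.25 * s * s - p
    if disc < 0.0:
        disc = 0.0
    root = np.sqrt(disc)
    Ra = 0.5 * s + root
    Rb = 0.5 * s - root
    return _pair_area(Ra, Rb, d)


@njit(cache=True)
def energy_of_mol(k, com, off, n, L, sigma2, eps, coeff, contact, area0,
                  molcut2):
    """Interaction energy of molecule k with all others."""
    u = 0.0
    for j in range(n):
        if j == k:
            continue
        dx = _min_image(com[j, 0] - com[k, 0], L)
        dy = _min_image(com[j, 1] - com[k, 1], L)
        dz = _min_image(com[j, 2] - com[k, 2], L)
        if dx * dx + dy * dy + dz * dz > molcut2:
            continue
        u += mol_pair_energy(com[k], off[k], com[j], off[j], L,
                             sigma2, eps, coeff, contact, area0)
        if u >= BIG:
            return BIG
    return u


@njit(cache=True)
def total_energy(com, off, L, sigma2, eps, coeff, contact, area0, molcut2):
    n = com.shape[0]
    u = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(com[j, 0] - com[i, 0], L)
            dy = _min_image(com[j, 1] - com[i, 1], L)
            dz = _min_image(com[j, 2] - com[i, 2], L)
            if dx * dx + dy * dy + dz * dz > molcut2:
                continue
            u += mol_pair_energy(com[i], off[i], com[j], off[j], L,
                                 sigma2, eps, coeff, contact, area0)
            if u >= BIG:
                return BIG
    return u


@njit(cache=True)
def scaled_total_energy(com, off, n, L, scale, sigma2, eps, coeff, contact,
                        area0, molcut2):
    """Total pair energy with centers of mass isotropically scaled
    (rigid molecules: offsets untouched) - virtual volume perturbation."""
    Ls = L * scale
    u = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image((com[j, 0] - com[i, 0]) * scale, Ls)
            dy = _min_image((com[j, 1] - com[i, 1]) * scale, Ls)
            dz = _min_image((com[j, 2] - com[i, 2]) * scale, Ls)
            if dx * dx + dy * dy + dz * dz > molcut2:
                continue
            nb = off.shape[1]
            for a in range(nb):
                for b in range(nb):
                    rx = dx + off[j, b, 0] - off[i, a, 0]
                    ry = dy + off[j, b, 1] - off[i, a, 1]
                    rz = dz + off[j, b, 2] - off[i, a, 2]
                    r2 = rx * rx + ry * ry + rz * rz
                    cab = contact[a, b]
                    if r2 >= cab * cab:
                        continue
                    if r2 < 1e-12:
                        return BIG
                    r = np.sqrt(r2)
                    s2 = sigma2[a, b] / r2
                    if s2 > 0.7937005259840998:
                        s6 = s2 * s2 * s2
                        u += 4.0 * eps[a, b] * (s6 * s6 - s6) + eps[a, b]
                    u += coeff[a, b] * (_pair_area_ab(a, b, r, contact, area0)
                                        - area0[a, b])
    return u


@njit(cache=True, inline="always")
def _rotate_inplace(off_k, ax, ay, az, angle):
    """Rodrigues rotation of one molecule's bead offsets about its COM."""
    nb = off_k.shape[0]
    ca = np.cos(angle)
    sa = np.sin(angle)
    for b in range(nb):
        px, py, pz = off_k[b, 0], off_k[b, 1], off_k[b, 2]
        dot = ax * px + ay * py + az * pz
        cx = ay * pz - az * py
        cy = az * px - ax * pz
        cz = ax * py - ay * px
        off_k[b, 0] = px * ca + cx * sa + ax * dot * (1.0 - ca)
        off_k[b, 1] = py * ca + cy * sa + ay * dot * (1.0 - ca)
        off_k[b, 2] = pz * ca + cz * sa + az * dot * (1.0 - ca)


@njit(cache=True, inline="always")
def _random_axis():
    while True:
        x = np.random.normal()
        y = np.random.normal()
        z = np.random.normal()
        n2 = x * x + y * y + z * z
        if n2 > 1e-12:
            n = np.sqrt(n2)
            return x / n, y / n, z / n


@njit(cache=True, inline="always")
def _random_rotation_matrix():
    q0 = np.random.normal()
    q1 = np.random.normal()
    q2 = np.random.normal()
    q3 = np.random.normal()
    n = np.sqrt(q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3)
    w, x, y, z = q0 / n, q1 / n, q2 / n, q3 / n
    M = np.empty((3, 3))
    M[0, 0] = 1 - 2 * (y * y + z * z)
    M[0, 1] = 2 * (x * y - w * z)
    M[0, 2] = 2 * (x * z + w * y)
    M[1, 0] = 2 * (x * y + w * z)
    M[1, 1] = 1 - 2 * (x * x + z * z)
    M[1, 2] = 2 * (y * z - w * x)
    M[2, 0] = 2 * (x * z - w * y)
    M[2, 1] = 2 * (y * z + w * x)
    M[2, 2] = 1 - 2 * (x * x + y * y)
    return M


@njit(cache=True)
def _find_cluster(seed, com, n, L, thresh2, member, stack):
    """Transitive closure of COM-distance <= threshold from the seed.

    Returns the cluster size, or -1 if the cluster percolates through
    the periodic boundaries (chain-unwrapped positions inconsistent or
    extent beyond L/2), in which case a move must be rejected."""
    for i in range(n):
        member[i] = 0
    unw = np.zeros((n, 3))
    member[seed] = 1
    stack[0] = seed
    top = 1
    size = 1
    ok = True
    while top > 0:
        top -= 1
        i = stack[top]
        for j in range(n):
            if j == i:
                continue
            dx = _min_image(com[j, 0] - com[i, 0], L)
            dy = _min_image(com[j, 1] - com[i, 1], L)
            dz = _min_image(com[j, 2] - com[i, 2], L)
            if dx * dx + dy * dy + dz * dz > thresh2:
                continue
            ux = unw[i, 0] + dx
            uy = unw[i, 1] + dy
            uz = unw[i, 2] + dz
            if member[j] == 1:
                # consistency: a second path to j must give the same
                # unwrapped position, otherwise the cluster wraps around
                if (abs(ux - unw[j, 0]) > 1e-9
                        or abs(uy - unw[j, 1]) > 1e-9
                        or abs(uz - unw[j, 2]) > 1e-9):
                    ok = False
                continue
            member[j] = 1
            unw[j, 0] = ux
            unw[j, 1] = uy
            unw[j, 2] = uz
            # extent guard: members within L/4 of the seed keep every
            # member-pair minimum-image distance equal to the true
            # distance, so rigid cluster motion preserves the internal
            # energy exactly
            if (ux * ux + uy * uy + uz * uz) > 0.0625 * L * L:
                ok = False
            stack[top] = j
            top += 1
            size += 1
    if not ok and size < n:
        return -1
    return size


@njit(cache=True)
def _cluster_external_energy(member, com, off, n, L, sigma2, eps, coeff,
                             contact, area0, molcut2):
    u = 0.0
    for i in range(n):
        if member[i] == 0:
            continue
        for j in range(n):
            if member[j] == 1:
                continue
            dx = _min_image(com[j, 0] - com[i, 0], L)
            dy = _min_image(com[j, 1] - com[i, 1], L)
            dz = _min_image(com[j, 2] - com[i, 2], L)
            if dx * dx + dy * dy + dz * dz > molcut2:
                continue
            u += mol_pair_energy(com[i], off[i], com[j], off[j], L,
                                 sigma2, eps, coeff, contact, area0)
            if u >= BIG:
                return BIG
    return u


@njit(cache=True)
def mc_chunk(com, off, n, L, sigma2, eps, coeff, contact, area0, molcut2,
             beta, u_one,
             max_trans, max_rot,
             clus_trans, clus_rot, clus_thresh,
             w_trans, w_rot, w_clus, w_gc,
             activity_density, body, n_steps, seed,
             member, stack):
    """Run ``n_steps`` attempted Metropolis moves in place.

    Move types: single-molecule translation / rotation, threshold
    cluster move with a membership guard, and (weight w_gc > 0) grand
    canonical insertion/deletion at molar-activity number density
    ``activity_density`` (1/Å³) including the one-body transfer energy
    ``u_one`` (kJ/mol).

    Returns (n, dU_accumulated, attempts[4], accepts[4]).

    ``seed`` >= 0 reseeds the kernel RNG stream; -1 continues the
    existing stream (used for chunked runs sharing one stream).
    """
    if seed >= 0:
        np.random.seed(seed)
    V = L * L * L
    wsum = w_trans + w_rot + w_clus + w_gc
    attempts = np.zeros(4, dtype=np.int64)
    accepts = np.zeros(4, dtype=np.int64)
    du_total = 0.0
    nb = off.shape[1]
    tmp_off = np.empty((nb, 3))
    capacity = com.shape[0]

    for _ in range(n_steps):
        r = np.random.random() * wsum
        if r < w_trans:
            mtype = 0
        elif r < w_trans + w_rot:
            mtype = 1
        elif r < w_trans + w_rot + w_clus:
            mtype = 2
        else:
            mtype = 3
        attempts[mtype] += 1

        if mtype <= 1:
            if n == 0:
                continue
            k = np.random.randint(n)
            u_old = energy_of_mol(k, com, off, n, L, sigma2, eps, coeff,
                                  contact, area0, molcut2)
            ox, oy, oz = com[k, 0], com[k, 1], com[k, 2]
            for b in range(nb):
                tmp_off[b, 0] = off[k, b, 0]
                tmp_off[b, 1] = off[k, b, 1]
                tmp_off[b, 2] = off[k, b, 2]
            if mtype == 0:
                ax, ay, az = _random_axis()
                mag = np.random.random() * max_trans
                com[k, 0] = (ox + ax * mag) % L
                com[k, 1] = (oy + ay * mag) % L
                com[k, 2] = (oz + az * mag) % L
            else:
                ax, ay, az = _random_axis()
                angle = (np.random.random() * 2.0 - 1.0) * max_rot
                _rotate_inplace(off[k], ax, ay, az, angle)
            u_new = energy_of_mol(k, com, off, n, L, sigma2, eps, coeff,
                                  contact, area0, molcut2)
            du = u_new - u_old
            if du < BIG and (du <= 0.0 or
                             np.random.random() < np.exp(-beta * du)):
                accepts[mtype] += 1
                du_total += du
            else:
                com[k, 0], com[k, 1], com[k, 2] = ox, oy, oz
                for b in range(nb):
                    off[k, b, 0] = tmp_off[b, 0]
                    off[k, b, 1] = tmp_off[b, 1]
                    off[k, b, 2] = tmp_off[b, 2]

        elif mtype == 2:
            if n == 0:
                continue
            seed_mol = np.random.randint(n)
            thresh2 = clus_thresh * clus_thresh
            size = _find_cluster(seed_mol, com, n, L, thresh2, member, stack)
            if size < 0:
                continue      # percolating cluster: rejected outright
            if size == n:
                # global rigid motion: dU = 0, counts as accepted
                ax, ay, az = _random_axis()
                mag = np.random.random() * clus_trans
                for i in range(n):
                    com[i, 0] = (com[i, 0] + ax * mag) % L
                    com[i, 1] = (com[i, 1] + ay * mag) % L
                    com[i, 2] = (com[i, 2] + az * mag) % L
                accepts[2] += 1
                continue
            u_old = _cluster_external_energy(member, com, off, n, L, sigma2,
                                             eps, coeff, contact, area0,
                                             molcut2)
            # save poses of members
            old_com = np.empty((size, 3))
            old_off = np.empty((size, nb, 3))
            idx = np.empty(size, dtype=np.int64)
            c = 0
            for i in range(n):
                if member[i] == 1:
                    idx[c] = i
                    old_com[c, 0] = com[i, 0]
                    old_com[c, 1] = com[i, 1]
                    old_com[c, 2] = com[i, 2]
                    for b in range(nb):
                        old_off[c, b, 0] = off[i, b, 0]
                        old_off[c, b, 1] = off[i, b, 1]
                        old_off[c, b, 2] = off[i, b, 2]
                    c += 1
            # rigid rotation about the seed COM + translation
            ax, ay, az = _random_axis()
            angle = (np.random.random() * 2.0 - 1.0) * clus_rot
            tx_, ty_, tz_ = _random_axis()
            mag = np.random.random() * clus_trans
            sx, sy, sz = com[seed_mol, 0], com[seed_mol, 1], com[seed_mol, 2]
            ca = np.cos(angle)
            sa = np.sin(angle)
            for c in range(size):
                i = idx[c]
                # min-image position relative to the seed
                px = _min_image(com[i, 0] - sx, L)
                py = _min_image(com[i, 1] - sy, L)
                pz = _min_image(com[i, 2] - sz, L)
                dot = ax * px + ay * py + az * pz
                cx = ay * pz - az * py
                cy = az * px - ax * pz
                cz = ax * py - ay * px
                qx = px * ca + cx * sa + ax * dot * (1.0 - ca)
                qy = py * ca + cy * sa + ay * dot * (1.0 - ca)
                qz = pz * ca + cz * sa + az * dot * (1.0 - ca)
                com[i, 0] = (sx + qx + tx_ * mag) % L
                com[i, 1] = (sy + qy + ty_ * mag) % L
                com[i, 2] = (sz + qz + tz_ * mag) % L
                _rotate_inplace(off[i], ax, ay, az, angle)
            # membership guard: cluster must be unchanged in new config
            member2 = np.empty_like(member)
            stack2 = np.empty_like(stack)
            for i in range(n):
                member2[i] = member[i]
            size_new = _find_cluster(seed_mol, com, n, L, thresh2, member,
                                     stack)
            same = size_new == size
            if same:
                for i in range(n):
                    if member[i] != member2[i]:
                        same = False
                        break
            accept = False
            if same:
                u_new = _cluster_external_energy(member, com, off, n, L,
                                                 sigma2, eps, coeff, contact,
                                                 area0, molcut2)
                du = u_new - u_old
                if du < BIG and (du <= 0.0 or
                                 np.random.random() < np.exp(-beta * du)):
                    accept = True
                    du_total += du
                    accepts[2] += 1
            if not accept:
                for c in range(size):
                    i = idx[c]
                    com[i, 0] = old_com[c, 0]
                    com[i, 1] = old_com[c, 1]
                    com[i, 2] = old_com[c, 2]
                    for b in range(nb):
                        off[i, b, 0] = old_off[c, b, 0]
                        off[i, b, 1] = old_off[c, b, 1]
                        off[i, b, 2] = old_off[c, b, 2]

        else:
            # grand canonical insert/delete, symmetric choice
            if np.random.random() < 0.5:
                if n >= capacity:
                    continue
                com[n, 0] = np.random.random() * L
                com[n, 1] = np.random.random() * L
                com[n, 2] = np.random.random() * L
                M = _random_rotation_matrix()
                for b in range(nb):
                    off[n, b, 0] = (M[0, 0] * body[b, 0] + M[0, 1] * body[b, 1]
                                    + M[0, 2] * body[b, 2])
                    off[n, b, 1] = (M[1, 0] * body[b, 0] + M[1, 1] * body[b, 1]
                                    + M[1, 2] * body[b, 2])
                    off[n, b, 2] = (M[2, 0] * body[b, 0] + M[2, 1] * body[b, 1]
                                    + M[2, 2] * body[b, 2])
                du = energy_of_mol(n, com, off, n + 1, L, sigma2, eps, coeff,
                                   contact, area0, molcut2) + u_one
                if du < BIG:
                    ratio = activity_density * V / (n + 1.0) \
                        * np.exp(-beta * du)
                    if ratio >= 1.0 or np.random.random() < ratio:
                        n += 1
                        du_total += du
                        accepts[3] += 1
            else:
                if n == 0:
                    continue
                k = np.random.randint(n)
                u_k = energy_of_mol(k, com, off, n, L, sigma2, eps, coeff,
                                    contact, area0, molcut2)
                if u_k >= BIG:
                    continue
                du = -(u_k + u_one)
                ratio = n / (activity_density * V) * np.exp(-beta * du)
                if ratio >= 1.0 or np.random.random() < ratio:
                    # move the last molecule into slot k
                    last = n - 1
                    if k != last:
                        com[k, 0] = com[last, 0]
                        com[k, 1] = com[last, 1]
                        com[k, 2] = com[last, 2]
                        for b in range(nb):
                            off[k, b, 0] = off[last, b, 0]
                            off[k, b, 1] = off[last, b, 1]
                            off[k, b, 2] = off[last, b, 2]
                    n -= 1
                    du_total += du
                    accepts[3] += 1

    return n, du_total, attempts, accepts


@njit(cache=True)
def widom_insertions(com, off, n, L, sigma2, eps, coeff, contact, area0,
                     molcut2, beta, u_one, body, n_insert, seed):
    """Sum of exp(-beta dU) over random trial insertions (Widom).

    The trial pose is uniform in the box with a uniform random
    orientation; dU includes the one-body transfer term.
    """
    if seed >= 0:
        np.random.seed(seed)
    nb = body.shape[0]
    capacity = com.shape[0]
    # trial molecule occupies the scratch slot after the last molecule
    acc = 0.0
    slot = n
    if slot >= capacity:
        return 0.0
    for _ in range(n_insert):
        com[slot, 0] = np.random.random() * L
        com[slot, 1] = np.random.random() * L
        com[slot, 2] = np.random.random() * L
        M = _random_rotation_matrix()
        for b in range(nb):
            off[slot, b, 0] = (M[0, 0] * body[b, 0] + M[0, 1] * body[b, 1]
                               + M[0, 2] * body[b, 2])
            off[slot, b, 1] = (M[1, 0] * body[b, 0] + M[1, 1] * body[b, 1]
                               + M[1, 2] * body[b, 2])
            off[slot, b, 2] = (M[2, 0] * body[b, 0] + M[2, 1] * body[b, 1]
                               + M[2, 2] * body[b, 2])
        du = energy_of_mol(slot, com, off, n + 1, L, sigma2, eps, coeff,
                           contact, area0, molcut2) + u_one
        if du < BIG:
            acc += np.exp(-beta * du)
    return acc


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def rdf_accumulate(com, n, L, dr, hist):
    """Accumulate COM-COM minimum-image distances into hist (r < L/2)."""
    half = 0.5 * L
    nbins = hist.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(com[j, 0] - com[i, 0], L)
            dy = _min_image(com[j, 1] - com[i, 1], L)
            dz = _min_image(com[j, 2] - com[i, 2], L)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < half:
                b = int(r / dr)
                if b < nbins:
                    hist[b] += 1.0
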