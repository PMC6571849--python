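"""Numba kernels for energies and Monte Carlo moves.

Everything here operates on plain arrays:

* ``pos``       -- (N, 3) float64 wrapped coordinates
* ``chain_id``  -- (N,) int64; consecutive beads with equal chain id are bonded
* ``partner``   -- (N,) int64 Go hybridization partner (-1 = none)
* ``P``         -- packed parameter vector (see index constants below)

The VMMC move is the symmetrized Whitelam-Geissler cluster algorithm: links
form with probability ``p1 = max(0, 1 - exp(-(E_fwd - E_old)))`` and become
full with probability ``min(1, p2/p1)`` where ``p2`` uses the inverse move;
a frustrated link rejects the whole move outright.  For purely pairwise
terms the remaining acceptance is exactly 1; the three-body bending term
cannot enter pairwise link formation, so boundary-straddling bend triplets
are handled by an explicit Metropolis factor ``exp(-dE_bend)``, which
preserves detailed balance.  Umbrella bias multiplies the acceptance by
``w_new/w_old`` evaluated on the (Qex, Qlig) state of the whole move.
"""

import numpy as np
from numba import njit

# P vector layout
BOND_K = 0
BOND_R0 = 1
BEND_K = 2
EV_SIG = 3
EV_EPS = 4
HYB_EPS = 5
HYB_RNG = 6
EL_AMP = 7
DEBYE = 8
EL_CUT = 9
E_CAP = 10
BOX = 11
NP_PARAMS = 12


@njit(cache=True)
def _mi(d, box):
    """Minimum-image of a single displacement component."""
    return d - box * np.floor(d / box + 0.5)


@njit(cache=True)
def _dist2(ax, ay, az, bx, by, bz, box):
    dx = _mi(ax - bx, box)
    dy = _mi(ay - by, box)
    dz = _mi(az - bz, box)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _nb_e(r2, is_hyb, P):
    """Non-bonded pair energy: WCA + truncated-shifted Yukawa (capped) + Go well."""
    e = 0.0
    if P[EV_EPS] > 0.0:
        sig2 = P[EV_SIG] * P[EV_SIG]
        rc2 = sig2 * 2.0 ** (1.0 / 3.0)
        if r2 < rc2:
            rr = r2 if r2 > 1e-12 else 1e-12
            s2 = sig2 / rr
            s6 = s2 * s2 * s2
            e += 4.0 * P[EV_EPS] * (s6 * s6 - s6) + P[EV_EPS]
    if P[EL_AMP] > 0.0:
        rc = P[EL_CUT]
        if r2 < rc * rc:
            r = np.sqrt(r2)
            if r < 1e-6:
                r = 1e-6
            lam = P[DEBYE]
            e += P[EL_AMP] * (np.exp(-r / lam) / r - np.exp(-rc / lam) / rc)
    if e > P[E_CAP]:
        e = P[E_CAP]
    if is_hyb and r2 < P[HYB_RNG] * P[HYB_RNG]:
        e -= P[HYB_EPS]
    return e


@njit(cache=True)
def _bond_e(r2, P):
    r = np.sqrt(r2)
    d = r - P[BOND_R0]
    return 0.5 * P[BOND_K] * d * d


@njit(cache=True)
def _pair_e_at(xi, yi, zi, j, pos, bonded, is_hyb, P):
    r2 = _dist2(xi, yi, zi, pos[j, 0], pos[j, 1], pos[j, 2], P[BOX])
    if bonded:
        return _bond_e(r2, P)
    return _nb_e(r2, is_hyb, P)


@njit(cache=True)
def _bend_e(pos, c, P):
    """Kratky-Porod bending energy of the angle centred at bead c."""
    box = P[BOX]
    ux = _mi(pos[c, 0] - pos[c - 1, 0], box)
    uy = _mi(pos[c, 1] - pos[c - 1, 1], box)
    uz = _mi(pos[c, 2] - pos[c - 1, 2], box)
    vx = _mi(pos[c + 1, 0] - pos[c, 0], box)
    vy = _mi(pos[c + 1, 1] - pos[c, 1], box)
    vz = _mi(pos[c + 1, 2] - pos[c, 2], box)
    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
    nv = np.sqrt(vx * vx + vy * vy + vz * vz)
    if nu < 1e-12 or nv < 1e-12:
        return 0.0
    cosq = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    if cosq > 1.0:
        cosq = 1.0
    elif cosq < -1.0:
        cosq = -1.0
    return P[BEND_K] * (1.0 - cosq)


@njit(cache=True)
def total_energy_arr(pos, chain_id, partner, P):
    N = pos.shape[0]
    box = P[BOX]
    e = 0.0
    for i in range(N - 1):
        if chain_id[i] == chain_id[i + 1]:
            r2 = _dist2(pos[i, 0], pos[i, 1], pos[i, 2],
                        pos[i + 1, 0], pos[i + 1, 1], pos[i + 1, 2], box)
            e += _bond_e(r2, P)
    if P[BEND_K] > 0.0:
        for c in range(1, N - 1):
            if chain_id[c - 1] == chain_id[c] and chain_id[c] == chain_id[c + 1]:
                e += _bend_e(pos, c, P)
    for i in range(N - 1):
        for j in range(i + 1, N):
            if j == i + 1 and chain_id[i] == chain_id[j]:
                continue
            r2 = _dist2(pos[i, 0], pos[i, 1], pos[i, 2],
                        pos[j, 0], pos[j, 1], pos[j, 2], box)
            e += _nb_e(r2, partner[i] == j, P)
    return e


@njit(cache=True)
def _local_e(pos, chain_id, partner, P, i):
    """All energy terms involving bead i at its current coordinates."""
    N = pos.shape[0]
    box = P[BOX]
    e = 0.0
    if i > 0 and chain_id[i - 1] == chain_id[i]:
        r2 = _dist2(pos[i, 0], pos[i, 1], pos[i, 2],
                    pos[i - 1, 0], pos[i - 1, 1], pos[i - 1, 2], box)
        e += _bond_e(r2, P)
    if i < N - 1 and chain_id[i] == chain_id[i + 1]:
        r2 = _dist2(pos[i, 0], pos[i, 1], pos[i, 2],
                    pos[i + 1, 0], pos[i + 1, 1], pos[i + 1, 2], box)
        e += _bond_e(r2, P)
    if P[BEND_K] > 0.0:
        for c in range(i - 1, i + 2):
            if 1 <= c <= N - 2 and chain_id[c - 1] == chain_id[c] \
                    and chain_id[c] == chain_id[c + 1]:
                e += _bend_e(pos, c, P)
    if P[EV_EPS] == 0.0 and P[EL_AMP] == 0.0:
        # sparse model: the only non-bonded term is the Go well
        j = partner[i]
        if j >= 0:
            r2 = _dist2(pos[i, 0], pos[i, 1], pos[i, 2],
                        pos[j, 0], pos[j, 1], pos[j, 2], box)
            e += _nb_e(r2, True, P)
        return e
    for j in range(N):
        if j == i:
            continue
        if (j == i - 1 or j == i + 1) and chain_id[j] == chain_id[i]:
            continue
        r2 = _dist2(pos[i, 0], pos[i, 1], pos[i, 2],
                    pos[j, 0], pos[j, 1], pos[j, 2], box)
        e += _nb_e(r2, partner[i] == j, P)
    return e


@njit(cache=True)
def arm_min_dist(pos, pairs, box):
    best = 1e300
    for k in range(pairs.shape[0]):
        a = pairs[k, 0]
        b = pairs[k, 1]
        r2 = _dist2(pos[a, 0], pos[a, 1], pos[a, 2],
                    pos[b, 0], pos[b, 1], pos[b, 2], box)
        if r2 < best:
            best = r2
    return np.sqrt(best)


@njit(cache=True)
def discretize_scalar(d, edges):
    q = 0
    for k in range(1, edges.shape[0]):
        if d >= edges[k]:
            q = k
        else:
            break
    return q


@njit(cache=True)
def _op(pos, ext_pairs, lig_pairs, edges, box):
    nmax = edges.shape[0] - 1
    if ext_pairs.shape[0] > 0:
        qe = discretize_scalar(arm_min_dist(pos, ext_pairs, box), edges)
    else:
        qe = nmax
    if lig_pairs.shape[0] > 0:
        ql = discretize_scalar(arm_min_dist(pos, lig_pairs, box), edges)
    else:
        ql = nmax
    return qe, ql


@njit(cache=True)
def _metropolis_move(pos, chain_id, partner, P, ext_pairs, lig_pairs, edges,
                     logw, qe, ql, max_trans):
    N = pos.shape[0]
    box = P[BOX]
    i = np.random.randint(N)
    e_old = _local_e(pos, chain_id, partner, P, i)
    ox = pos[i, 0]
    oy = pos[i, 1]
    oz = pos[i, 2]
    pos[i, 0] = (ox + (2.0 * np.random.random() - 1.0) * max_trans) % box
    pos[i, 1] = (oy + (2.0 * np.random.random() - 1.0) * max_trans) % box
    pos[i, 2] = (oz + (2.0 * np.random.random() - 1.0) * max_trans) % box
    e_new = _local_e(pos, chain_id, partner, P, i)
    qe2, ql2 = _op(pos, ext_pairs, lig_pairs, edges, box)
    arg = -(e_new - e_old) + logw[qe2, ql2] - logw[qe, ql]
    if arg >= 0.0 or np.random.random() < np.exp(arg):
        return True, qe2, ql2
    pos[i, 0] = ox
    pos[i, 1] = oy
    pos[i, 2] = oz
    return False, qe, ql


@njit(cache=True)
def _rot_matrix(ax, ay, az, ang):
    c = np.cos(ang)
    s = np.sin(ang)
    t = 1.0 - c
    R = np.empty((3, 3))
    R[0, 0] = c + ax * ax * t
    R[0, 1] = ax * ay * t - az * s
    R[0, 2] = ax * az * t + ay * s
    R[1, 0] = ax * ay * t + az * s
    R[1, 1] = c + ay * ay * t
    R[1, 2] = ay * az * t - ax * s
    R[2, 0] = ax * az * t - ay * s
    R[2, 1] = ay * az * t + ax * s
    R[2, 2] = c + az * az * t
    return R


@njit(cache=True)
def _apply_map(x, y, z, is_rot, dx, dy, dz, R, px, py, pz, box):
    """Forward (or, with negated d / transposed R, inverse) move map."""
    if not is_rot:
        return x + dx, y + dy, z + dz
    rx = _mi(x - px, box)
    ry = _mi(y - py, box)
    rz = _mi(z - pz, box)
    nx = R[0, 0] * rx + R[0, 1] * ry + R[0, 2] * rz
    ny = R[1, 0] * rx + R[1, 1] * ry + R[1, 2] * rz
    nz = R[2, 0] * rx + R[2, 1] * ry + R[2, 2] * rz
    return px + nx, py + ny, pz + nz


@njit(cache=True)
def _link_pair(i, j, xi, yi, zi, fx, fy, fz, rx, ry, rz, pos, chain_id,
               partner, P, skip2, in_c, members, stack, fail_j, fail_df,
               fail_dr, n_mem, n_st, n_fail, cap):
    """Run the symmetrized link test for pair (i in cluster, j outside).

    Returns (status, n_mem, n_st, n_fail): status 0 = continue,
    1 = frustrated link (reject move), 2 = cluster cap exceeded.
    """
    box = P[BOX]
    bonded = (j == i - 1 or j == i + 1) and chain_id[j] == chain_id[i]
    is_h = partner[i] == j
    if not bonded:
        r2o = _dist2(xi, yi, zi, pos[j, 0], pos[j, 1], pos[j, 2], box)
        if r2o > skip2:
            return 0, n_mem, n_st, n_fail   # i moves less than `reach`
        r2f = _dist2(fx, fy, fz, pos[j, 0], pos[j, 1], pos[j, 2], box)
        r2r = _dist2(rx, ry, rz, pos[j, 0], pos[j, 1], pos[j, 2], box)
        e_old = _nb_e(r2o, is_h, P)
        e_fwd = _nb_e(r2f, is_h, P)
        e_rev = _nb_e(r2r, is_h, P)
    else:
        e_old = _pair_e_at(xi, yi, zi, j, pos, True, is_h, P)
        e_fwd = _pair_e_at(fx, fy, fz, j, pos, True, is_h, P)
        e_rev = _pair_e_at(rx, ry, rz, j, pos, True, is_h, P)
    de_f = e_fwd - e_old
    de_r = e_rev - e_old
    if de_f > 0.0:
        p1 = 1.0 - np.exp(-de_f)
        if np.random.random() < p1:
            p2 = 0.0 if de_r <= 0.0 else 1.0 - np.exp(-de_r)
            if p2 >= p1 or np.random.random() < p2 / p1:
                in_c[j] = True
                members[n_mem] = j
                n_mem += 1
                if n_mem > cap:
                    return 2, n_mem, n_st, n_fail
                stack[n_st] = j
                n_st += 1
                return 0, n_mem, n_st, n_fail
            return 1, n_mem, n_st, n_fail
    if de_f != 0.0 or de_r != 0.0:
        # tested pair that stayed unlinked: if j is later recruited through
        # another member, the pair becomes cluster-internal and its
        # forward/reverse no-link probabilities do not cancel; record for
        # the acceptance correction applied after construction.
        fail_j[n_fail] = j
        fail_df[n_fail] = de_f
        fail_dr[n_fail] = de_r
        n_fail += 1
    return 0, n_mem, n_st, n_fail


@njit(cache=True)
def _vmmc_move(pos, chain_id, partner, P, ext_pairs, lig_pairs, edges,
               logw, qe, ql, max_trans, max_rot, rot_prob, big_trans, p_big,
               cap, fail_j, fail_df, fail_dr, in_c, members, stack, old):
    N = pos.shape[0]
    box = P[BOX]
    in_c[:] = False
    seed_bead = np.random.randint(N)
    in_c[seed_bead] = True
    members[0] = seed_bead
    n_mem = 1
    stack[0] = seed_bead
    n_st = 1

    # move map
    is_rot = np.random.random() < rot_prob
    px = pos[seed_bead, 0]
    py = pos[seed_bead, 1]
    pz = pos[seed_bead, 2]
    dx = 0.0
    dy = 0.0
    dz = 0.0
    ang = 0.0
    R = np.eye(3)
    if is_rot:
        nx = np.random.normal()
        ny = np.random.normal()
        nz = np.random.normal()
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        if nn < 1e-12:
            nx, ny, nz, nn = 1.0, 0.0, 0.0, 1.0
        ang = (2.0 * np.random.random() - 1.0) * max_rot
        R = _rot_matrix(nx / nn, ny / nn, nz / nn, ang)
    else:
        nx = np.random.normal()
        ny = np.random.normal()
        nz = np.random.normal()
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        if nn < 1e-12:
            nx, ny, nz, nn = 1.0, 0.0, 0.0, 1.0
        mt = max_trans
        if p_big > 0.0 and np.random.random() < p_big:
            mt = big_trans  # occasional large displacement for chain diffusion
        rad = mt * np.random.random() ** (1.0 / 3.0)
        dx = rad * nx / nn
        dy = rad * ny / nn
        dz = rad * nz / nn
    Rt = R.T.copy()
    two_sin_half = 2.0 * np.abs(np.sin(0.5 * ang)) if is_rot else 0.0
    sparse = P[EV_EPS] == 0.0 and P[EL_AMP] == 0.0

    # interaction-relevance cutoff for the quick pair skip
    rcut = P[HYB_RNG]
    wca = P[EV_SIG] * 2.0 ** (1.0 / 6.0)
    if P[EV_EPS] > 0.0 and wca > rcut:
        rcut = wca
    if P[EL_AMP] > 0.0 and P[EL_CUT] > rcut:
        rcut = P[EL_CUT]
    rcut2 = rcut * rcut

    # cluster construction
    n_fail = 0
    while n_st > 0:
        n_st -= 1
        i = stack[n_st]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        fx, fy, fz = _apply_map(xi, yi, zi, is_rot, dx, dy, dz, R, px, py, pz, box)
        rx, ry, rz = _apply_map(xi, yi, zi, is_rot, -dx, -dy, -dz, Rt, px, py, pz, box)
        if is_rot:
            reach = two_sin_half * np.sqrt(_dist2(xi, yi, zi, px, py, pz, box))
        else:
            reach = rad
        skip = rcut + reach
        skip2 = skip * skip
        if sparse:
            # only bonds and the Go partner interact: O(1) candidates
            for c in range(3):
                if c == 0:
                    j = i - 1
                elif c == 1:
                    j = i + 1
                else:
                    j = partner[i]
                if j < 0 or j >= N or in_c[j]:
                    continue
                if c < 2 and chain_id[j] != chain_id[i]:
                    continue
                status, n_mem, n_st, n_fail = _link_pair(
                    i, j, xi, yi, zi, fx, fy, fz, rx, ry, rz, pos, chain_id,
                    partner, P, skip2, in_c, members, stack,
                    fail_j, fail_df, fail_dr, n_mem, n_st, n_fail, cap)
                if status == 1:
                    return False, False, qe, ql   # frustrated link: reject
                if status == 2:
                    return False, True, qe, ql    # capped: logged auto-reject
        else:
            for j in range(N):
                if in_c[j]:
                    continue
                # cheap inline pre-screen: far, non-bonded, non-partner
                # pairs cannot interact before or after the move
                if partner[i] != j and not (
                        (j == i - 1 or j == i + 1)
                        and chain_id[j] == chain_id[i]):
                    if _dist2(xi, yi, zi, pos[j, 0], pos[j, 1], pos[j, 2],
                              box) > skip2:
                        continue
                status, n_mem, n_st, n_fail = _link_pair(
                    i, j, xi, yi, zi, fx, fy, fz, rx, ry, rz, pos, chain_id,
                    partner, P, skip2, in_c, members, stack,
                    fail_j, fail_df, fail_dr, n_mem, n_st, n_fail, cap)
                if status == 1:
                    return False, False, qe, ql
                if status == 2:
                    return False, True, qe, ql

    # boundary-straddling bending triplets (3-body term, Metropolis factor)
    de_bend = 0.0
    if P[BEND_K] > 0.0 and n_mem < N:
        for c in range(1, N - 1):
            if chain_id[c - 1] == chain_id[c] and chain_id[c] == chain_id[c + 1]:
                m = 0
                if in_c[c - 1]:
                    m += 1
                if in_c[c]:
                    m += 1
                if in_c[c + 1]:
                    m += 1
                if 0 < m < 3:
                    de_bend -= _bend_e(pos, c, P)

    for k in range(n_mem):
        i = members[k]
        old[k, 0] = pos[i, 0]
        old[k, 1] = pos[i, 1]
        old[k, 2] = pos[i, 2]
        nx2, ny2, nz2 = _apply_map(old[k, 0], old[k, 1], old[k, 2], is_rot,
                                   dx, dy, dz, R, px, py, pz, box)
        pos[i, 0] = nx2 % box
        pos[i, 1] = ny2 % box
        pos[i, 2] = nz2 % box

    if P[BEND_K] > 0.0 and n_mem < N:
        for c in range(1, N - 1):
            if chain_id[c - 1] == chain_id[c] and chain_id[c] == chain_id[c + 1]:
                m = 0
                if in_c[c - 1]:
                    m += 1
                if in_c[c]:
                    m += 1
                if in_c[c + 1]:
                    m += 1
                if 0 < m < 3:
                    de_bend += _bend_e(pos, c, P)

    # acceptance correction for unlinked tested pairs that ended inside the
    # cluster: ratio of reverse to forward no-link probabilities
    corr = 0.0
    for k in range(n_fail):
        if in_c[fail_j[k]]:
            corr += min(0.0, -fail_dr[k]) - min(0.0, -fail_df[k])

    qe2, ql2 = _op(pos, ext_pairs, lig_pairs, edges, box)
    arg = corr - de_bend + logw[qe2, ql2] - logw[qe, ql]
    if arg >= 0.0 or np.random.random() < np.exp(arg):
        return True, False, qe2, ql2
    for k in range(n_mem):
        i = members[k]
        pos[i, 0] = old[k, 0]
        pos[i, 1] = old[k, 1]
        pos[i, 2] = old[k, 2]
    return False, False, qe, ql


@njit(cache=True)
def run_mc(pos, chain_id, partner, P, ext_pairs, lig_pairs, edges, logw,
           use_vmmc, max_trans, max_rot, rot_prob, big_trans, p_big, cap,
           n_equil, n_steps, stride, seed, hist, traj_qe, traj_ql,
           wl_f, wl_sunk, wl_temper):
    """Run the sampler; accumulates the OP histogram over production steps
    and records the OP trajectory every ``stride`` steps.

    With ``wl_f > 0`` the log-weight of the currently occupied cell is
    lowered after every move (Wang-Landau updating, mutating ``logw`` in
    place); used only during weight adaptation, never in production.  With
    ``wl_temper > 0`` the decrement is well-tempered: it scales by
    ``exp(-sunk/wl_temper)`` where ``wl_sunk`` accumulates each cell's
    total sinking, so a walker trapped in a deep basin cannot oversink it
    past the tempering scale -- plain Wang-Landau at a large ``f`` can
    carve fake tens-of-kT walls during a single slow escape, which later
    stages cannot erode.

    Returns (n_accepted, n_cap_rejected, n_recorded); acceptance is counted
    over all equilibration + production moves.
    """
    if seed >= 0:
        np.random.seed(seed)
    box = P[BOX]
    qe, ql = _op(pos, ext_pairs, lig_pairs, edges, box)
    n_acc = 0
    n_cap = 0
    rec = 0
    N = pos.shape[0]
    fail_j = np.empty(N * N, np.int64)
    fail_df = np.empty(N * N, np.float64)
    fail_dr = np.empty(N * N, np.float64)
    in_c = np.zeros(N, np.bool_)
    members = np.empty(N, np.int64)
    stack = np.empty(N, np.int64)
    old = np.empty((N, 3))
    total = n_equil + n_steps
    for step in range(total):
        if use_vmmc:
            acc, capped, qe, ql = _vmmc_move(pos, chain_id, partner, P,
                                             ext_pairs, lig_pairs, edges, logw,
                                             qe, ql, max_trans, max_rot,
                                             rot_prob, big_trans, p_big, cap,
                                             fail_j, fail_df, fail_dr,
                                             in_c, members, stack, old)
            if capped:
                n_cap += 1
        else:
            acc, qe, ql = _metropolis_move(pos, chain_id, partner, P,
                                           ext_pairs, lig_pairs, edges, logw,
                                           qe, ql, max_trans)
        if acc:
            n_acc += 1
        if wl_f > 0.0:
            if wl_temper > 0.0:
                d = wl_f * np.exp(-wl_sunk[qe, ql] / wl_temper)
                logw[qe, ql] -= d
                wl_sunk[qe, ql] += d
            else:
                logw[qe, ql] -= wl_f
        if step >= n_equil:
            hist[qe, ql] += 1
            if stride > 0 and (step - n_equil) % stride == 0 \
                    and rec < traj_qe.shape[0]:
                traj_qe[rec] = qe
                traj_ql[rec] = ql
                rec += 1
    return n_acc, n_cap, rec
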