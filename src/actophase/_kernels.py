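"""Numba inner loops for the active-polymer Langevin engine.

All kernels work in reduced units (sigma = m = kBT = 1).  Positions live in a
centered periodic box, components in [-L/2, L/2).  Beads are stored
chain-major, so the bonded pairs are exactly (i, i+1) with equal chain id;
bonded pairs are excluded from the LJ pair list and handled by the FENE loop.

Nonbonded interactions run off a Verlet pair list built by cell binning with
a skin; the list is rebuilt whenever any bead has moved farther than half the
skin since the last build.  Forces agree with the all-pairs reference to
machine precision.

Status codes:
    0 — ok
    1 — FENE bond reached R0 (overstretch)
    2 — singular pair overlap (r ~ 0 with capping disabled)
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERSTRETCH = 1
STATUS_OVERLAP = 2
STATUS_LIST_OVERFLOW = 3

SKIN = 0.45  # pair-list skin in sigma; rebuild at half-skin displacement


@njit(cache=True, fastmath=True)
def _build_pairs(pos, chain_id, box, rlistsq, ncell, cell_head, cell_next,
                 pi, pj):
    """Cell-binned half pair list within sqrt(rlistsq); returns count or -1.

    Bonded (i, i+1 same-chain) pairs are excluded.  Requires >= 3 cells per
    axis on every dimension with more than one cell; callers guarantee this
    by construction of ncell.
    """
    n = pos.shape[0]
    ncx, ncy, ncz = ncell[0], ncell[1], ncell[2]
    ntot = ncx * ncy * ncz
    for c in range(ntot):
        cell_head[c] = -1
    for i in range(n):
        cx = np.int64((pos[i, 0] / box[0] + 0.5) * ncx)
        cy = np.int64((pos[i, 1] / box[1] + 0.5) * ncy)
        cz = np.int64((pos[i, 2] / box[2] + 0.5) * ncz)
        if cx >= ncx:
            cx = ncx - 1
        elif cx < 0:
            cx = 0
        if cy >= ncy:
            cy = ncy - 1
        elif cy < 0:
            cy = 0
        if cz >= ncz:
            cz = ncz - 1
        elif cz < 0:
            cz = 0
        c = (cz * ncy + cy) * ncx + cx
        cell_next[i] = cell_head[c]
        cell_head[c] = i

    offs = np.empty((13, 3), dtype=np.int64)
    offs[0, 0] = 1; offs[0, 1] = 0; offs[0, 2] = 0
    offs[1, 0] = -1; offs[1, 1] = 1; offs[1, 2] = 0
    offs[2, 0] = 0; offs[2, 1] = 1; offs[2, 2] = 0
    offs[3, 0] = 1; offs[3, 1] = 1; offs[3, 2] = 0
    offs[4, 0] = -1; offs[4, 1] = -1; offs[4, 2] = 1
    offs[5, 0] = 0; offs[5, 1] = -1; offs[5, 2] = 1
    offs[6, 0] = 1; offs[6, 1] = -1; offs[6, 2] = 1
    offs[7, 0] = -1; offs[7, 1] = 0; offs[7, 2] = 1
    offs[8, 0] = 0; offs[8, 1] = 0; offs[8, 2] = 1
    offs[9, 0] = 1; offs[9, 1] = 0; offs[9, 2] = 1
    offs[10, 0] = -1; offs[10, 1] = 1; offs[10, 2] = 1
    offs[11, 0] = 0; offs[11, 1] = 1; offs[11, 2] = 1
    offs[12, 0] = 1; offs[12, 1] = 1; offs[12, 2] = 1

    cap = pi.shape[0]
    cnt = 0
    bx, by, bz = box[0], box[1], box[2]
    ibx, iby, ibz = 1.0 / bx, 1.0 / by, 1.0 / bz
    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                c = (cz * ncy + cy) * ncx + cx
                i = cell_head[c]
                while i >= 0:
                    xi = pos[i, 0]
                    yi = pos[i, 1]
                    zi = pos[i, 2]
                    ci = chain_id[i]
                    # home cell: beads after i in the list
                    j = cell_next[i]
                    while j >= 0:
                        dx = xi - pos[j, 0]
                        dy = yi - pos[j, 1]
                        dz = zi - pos[j, 2]
                        dx -= bx * np.rint(dx * ibx)
                        dy -= by * np.rint(dy * iby)
                        dz -= bz * np.rint(dz * ibz)
                        if dx * dx + dy * dy + dz * dz < rlistsq:
                            dij = i - j
                            if ci != chain_id[j] or (dij != 1 and dij != -1):
                                if cnt >= cap:
                                    return -1
                                pi[cnt] = i
                                pj[cnt] = j
                                cnt += 1
                        j = cell_next[j]
                    for k in range(13):
                        ox = cx + offs[k, 0]
                        oy = cy + offs[k, 1]
                        oz = cz + offs[k, 2]
                        if ox < 0:
                            ox += ncx
                        elif ox >= ncx:
                            ox -= ncx
                        if oy < 0:
                            oy += ncy
                        elif oy >= ncy:
                            oy -= ncy
                        if oz < 0:
                            oz += ncz
                        elif oz >= ncz:
                            oz -= ncz
                        c2 = (oz * ncy + oy) * ncx + ox
                        j = cell_head[c2]
                        while j >= 0:
                            dx = xi - pos[j, 0]
                            dy = yi - pos[j, 1]
                            dz = zi - pos[j, 2]
                            dx -= bx * np.rint(dx * ibx)
                            dy -= by * np.rint(dy * iby)
                            dz -= bz * np.rint(dz * ibz)
                            if dx * dx + dy * dy + dz * dz < rlistsq:
                                dij = i - j
                                if ci != chain_id[j] or (dij != 1 and dij != -1):
                                    if cnt >= cap:
                                        return -1
                                    pi[cnt] = i
                                    pj[cnt] = j
                                    cnt += 1
                            j = cell_next[j]
                    i = cell_next[i]
    return cnt


@njit(cache=True, fastmath=True)
def _build_pairs_allpairs(pos, chain_id, box, rlistsq, pi, pj):
    """O(N^2) pair-list build for boxes too small for cell binning."""
    n = pos.shape[0]
    cap = pi.shape[0]
    cnt = 0
    bx, by, bz = box[0], box[1], box[2]
    ibx, iby, ibz = 1.0 / bx, 1.0 / by, 1.0 / bz
    for i in range(n):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j - i == 1:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= bx * np.rint(dx * ibx)
            dy -= by * np.rint(dy * iby)
            dz -= bz * np.rint(dz * ibz)
            if dx * dx + dy * dy + dz * dz < rlistsq:
                if cnt >= cap:
                    return -1
                pi[cnt] = i
                pj[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def _pair_scalars(pos, box, eps, rcutsq, pi, pj, npairs, dxk, dyk, dzk, fk):
    """Minimum-image separations and LJ force factors for listed pairs.

    Branch-light so LLVM can vectorize; pairs beyond the cutoff get a zero
    factor, near-overlaps are clamped (the caller detects them afterwards).
    """
    bx, by, bz = box[0], box[1], box[2]
    ibx, iby, ibz = 1.0 / bx, 1.0 / by, 1.0 / bz
    c24 = 24.0 * eps
    for k in range(npairs):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= bx * np.rint(dx * ibx)
        dy -= by * np.rint(dy * iby)
        dz -= bz * np.rint(dz * ibz)
        rsq = dx * dx + dy * dy + dz * dz
        inside = 1.0 if rsq < rcutsq else 0.0
        rs = rsq if rsq > 1e-8 else 1e-8
        sr2 = 1.0 / rs
        sr6 = sr2 * sr2 * sr2
        fk[k] = c24 * (2.0 * sr6 * sr6 - sr6) * sr2 * inside
        dxk[k] = dx
        dyk[k] = dy
        dzk[k] = dz


@njit(cache=True)
def _forces_pairs(pos, chain_id, fz, box, eps, rcutsq, kfene, r0sq,
                  bias_k, fcap, F, pi, pj, npairs, dxk, dyk, dzk, fk):
    """Forces (bias + active + LJ over the pair list + FENE/WCA bonds)."""
    n = pos.shape[0]
    bx, by, bz = box[0], box[1], box[2]
    ibx, iby, ibz = 1.0 / bx, 1.0 / by, 1.0 / bz
    for i in range(n):
        F[i, 0] = -bias_k * pos[i, 0]
        F[i, 1] = -bias_k * pos[i, 1]
        F[i, 2] = -bias_k * pos[i, 2] + fz[i]
    c24 = 24.0 * eps
    if fcap <= 0.0:
        _pair_scalars(pos, box, eps, rcutsq, pi, pj, npairs, dxk, dyk, dzk, fk)
        for k in range(npairs):
            f = fk[k]
            if f == 0.0:
                continue
            rsq = dxk[k] * dxk[k] + dyk[k] * dyk[k] + dzk[k] * dzk[k]
            if rsq < 1e-10:
                return STATUS_OVERLAP
            i = pi[k]
            j = pj[k]
            F[i, 0] += f * dxk[k]
            F[i, 1] += f * dyk[k]
            F[i, 2] += f * dzk[k]
            F[j, 0] -= f * dxk[k]
            F[j, 1] -= f * dyk[k]
            F[j, 2] -= f * dzk[k]
    else:
        # capped path (initialization pushes only); branches are fine here
        for k in range(npairs):
            i = pi[k]
            j = pj[k]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= bx * np.rint(dx * ibx)
            dy -= by * np.rint(dy * iby)
            dz -= bz * np.rint(dz * ibz)
            rsq = dx * dx + dy * dy + dz * dz
            if rsq >= rcutsq:
                continue
            if rsq < 0.25:
                rsq = 0.25
            sr2 = 1.0 / rsq
            sr6 = sr2 * sr2 * sr2
            f = c24 * (2.0 * sr6 * sr6 - sr6) * sr2
            fmag = np.abs(f) * np.sqrt(rsq)
            if fmag > fcap:
                f *= fcap / fmag
            F[i, 0] += f * dx
            F[i, 1] += f * dy
            F[i, 2] += f * dz
            F[j, 0] -= f * dx
            F[j, 1] -= f * dy
            F[j, 2] -= f * dz
    # FENE + WCA bonds: the finitely extensible bond carries its own
    # short-range repulsion (nonbonded LJ excludes bonded pairs); without
    # it bonds would collapse toward r = 0
    wca_rcsq = 2.0 ** (1.0 / 3.0)
    for i in range(n - 1):
        if chain_id[i] != chain_id[i + 1]:
            continue
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        dx -= bx * np.rint(dx * ibx)
        dy -= by * np.rint(dy * iby)
        dz -= bz * np.rint(dz * ibz)
        rsq = dx * dx + dy * dy + dz * dz
        if rsq >= r0sq:
            return STATUS_OVERSTRETCH
        f = -kfene / (1.0 - rsq / r0sq)
        if rsq < wca_rcsq:
            rsq_eff = rsq
            if fcap > 0.0 and rsq_eff < 0.25:
                rsq_eff = 0.25
            sr2 = 1.0 / rsq_eff
            sr6 = sr2 * sr2 * sr2
            fw = c24 * (2.0 * sr6 * sr6 - sr6) * sr2
            if fcap > 0.0:
                fmag = np.abs(fw) * np.sqrt(rsq_eff)
                if fmag > fcap:
                    fw *= fcap / fmag
            f += fw
        F[i, 0] += f * dx
        F[i, 1] += f * dy
        F[i, 2] += f * dz
        F[i + 1, 0] -= f * dx
        F[i + 1, 1] -= f * dy
        F[i + 1, 2] -= f * dz
    return STATUS_OK


@njit(cache=True)
def _forces_allpairs(pos, chain_id, fz, box, eps, rcutsq, kfene, r0sq,
                     bias_k, fcap, F):
    """Reference force evaluation without any neighbor structure."""
    n = pos.shape[0]
    cap = n * (n - 1) // 2 + 1
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    cnt = _build_pairs_allpairs(pos, chain_id, box, rcutsq, pi, pj)
    dxk = np.empty(cap)
    dyk = np.empty(cap)
    dzk = np.empty(cap)
    fk = np.empty(cap)
    return _forces_pairs(pos, chain_id, fz, box, eps, rcutsq, kfene, r0sq,
                         bias_k, fcap, F, pi, pj, cnt, dxk, dyk, dzk, fk)


@njit(cache=True)
def _wrap(pos, box):
    n = pos.shape[0]
    for i in range(n):
        for k in range(3):
            L = box[k]
            x = pos[i, k]
            if x < -0.5 * L or x >= 0.5 * L:
                pos[i, k] = x - L * np.floor(x / L + 0.5)


@njit(cache=True)
def run_chunk(pos, vel, chain_id, fz, box, nsteps, dt, gamma, kT,
              eps, rcutsq, kfene, r0sq, bias_k, fcap, vcap, seed,
              ncell, cell_head, cell_next, F):
    """Advance nsteps of BAOAB Langevin dynamics in place.

    Forces are evaluated once per step; with gamma = 0 the O-step is the
    identity and the scheme reduces to plain (energy-conserving)
    velocity-Verlet.  vcap > 0 clamps per-bead speed (initialization pushes
    only).  Returns (status, v2_mean): the per-step average of sum_i |v_i|^2.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    use_cells = ncell[0] >= 3 and ncell[1] >= 3 and ncell[2] >= 3
    rcut = np.sqrt(rcutsq)
    rlist = rcut + SKIN
    rlistsq = rlist * rlist
    half_skin_sq = 0.25 * SKIN * SKIN
    cap = max(n * 120, 4096)
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    ref = pos.copy()

    if use_cells:
        npairs = _build_pairs(pos, chain_id, box, rlistsq, ncell, cell_head,
                              cell_next, pi, pj)
    else:
        npairs = _build_pairs_allpairs(pos, chain_id, box, rlistsq, pi, pj)
    if npairs < 0:
        return STATUS_LIST_OVERFLOW, 0.0

    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(kT * (1.0 - c1 * c1))
    else:
        c1 = 1.0
        c2 = 0.0
    half = 0.5 * dt
    bx, by, bz = box[0], box[1], box[2]
    ibx, iby, ibz = 1.0 / bx, 1.0 / by, 1.0 / bz

    dxk = np.empty(cap)
    dyk = np.empty(cap)
    dzk = np.empty(cap)
    fk = np.empty(cap)
    status = _forces_pairs(pos, chain_id, fz, box, eps, rcutsq, kfene, r0sq,
                           bias_k, fcap, F, pi, pj, npairs, dxk, dyk, dzk, fk)
    if status != STATUS_OK:
        return status, 0.0

    v2_acc = 0.0
    for _ in range(nsteps):
        for i in range(n):
            vel[i, 0] += half * F[i, 0]
            vel[i, 1] += half * F[i, 1]
            vel[i, 2] += half * F[i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if c2 > 0.0:
            noise = np.random.standard_normal(3 * n)
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * noise[3 * i]
                vel[i, 1] = c1 * vel[i, 1] + c2 * noise[3 * i + 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise[3 * i + 2]
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        _wrap(pos, box)

        # rebuild the pair list when any displacement exceeds half the skin
        dmax = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            dx -= bx * np.rint(dx * ibx)
            dy -= by * np.rint(dy * iby)
            dz -= bz * np.rint(dz * ibz)
            dsq = dx * dx + dy * dy + dz * dz
            if dsq > dmax:
                dmax = dsq
        if dmax > half_skin_sq:
            if use_cells:
                npairs = _build_pairs(pos, chain_id, box, rlistsq, ncell,
                                      cell_head, cell_next, pi, pj)
            else:
                npairs = _build_pairs_allpairs(pos, chain_id, box, rlistsq,
                                               pi, pj)
            if npairs < 0:
                return STATUS_LIST_OVERFLOW, v2_acc / max(nsteps, 1)
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]

        status = _forces_pairs(pos, chain_id, fz, box, eps, rcutsq, kfene,
                               r0sq, bias_k, fcap, F, pi, pj, npairs,
                               dxk, dyk, dzk, fk)
        if status != STATUS_OK:
            return status, v2_acc / max(nsteps, 1)
        v2 = 0.0
        for i in range(n):
            vel[i, 0] += half * F[i, 0]
            vel[i, 1] += half * F[i, 1]
            vel[i, 2] += half * F[i, 2]
            if vcap > 0.0:
                sp = np.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
                if sp > vcap:
                    sc = vcap / sp
                    vel[i, 0] *= sc
                    vel[i, 1] *= sc
                    vel[i, 2] *= sc
            v2 += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
        v2_acc += v2
    return STATUS_OK, v2_acc / max(nsteps, 1)


@njit(cache=True)
def total_energy(pos, vel, chain_id, box, eps, rcutsq, kfene, r0sq, shift):
    """All-pairs total energy (KE + LJ + FENE) for small-system checks."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n):
        e += 0.5 * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    sr2c = 1.0 / rcutsq
    sr6c = sr2c * sr2c * sr2c
    ecut = 4.0 * eps * (sr6c * sr6c - sr6c)
    bx, by, bz = box[0], box[1], box[2]
    ibx, iby, ibz = 1.0 / bx, 1.0 / by, 1.0 / bz
    for i in range(n):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j - i == 1:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= bx * np.rint(dx * ibx)
            dy -= by * np.rint(dy * iby)
            dz -= bz * np.rint(dz * ibz)
            rsq = dx * dx + dy * dy + dz * dz
            if rsq >= rcutsq:
                continue
            sr2 = 1.0 / rsq
            sr6 = sr2 * sr2 * sr2
            e += 4.0 * eps * (sr6 * sr6 - sr6)
            if shift:
                e -= ecut
    wca_rcsq = 2.0 ** (1.0 / 3.0)
    for i in range(n - 1):
        if chain_id[i] != chain_id[i + 1]:
            continue
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        dx -= bx * np.rint(dx * ibx)
        dy -= by * np.rint(dy * iby)
        dz -= bz * np.rint(dz * ibz)
        rsq = dx * dx + dy * dy + dz * dz
        e += -0.5 * kfene * r0sq * np.log(1.0 - rsq / r0sq)
        if rsq < wca_rcsq:
            sr2 = 1.0 / rsq
            sr6 = sr2 * sr2 * sr2
            e += 4.0 * eps * (sr6 * sr6 - sr6) + eps
    return e
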