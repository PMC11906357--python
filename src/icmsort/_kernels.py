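"""Numba kernels for the Poissonian cellular Potts lattice.

Hot-path routines operate on flat per-label arrays: ``lab`` is the 3D int32
label grid, ``typ[label]`` the voxel type of each label, ``vol[label]`` the
current voxel count and ``tgt[label]`` the preferred volume V̄.  Labels 0 and 1
are reserved for the medium and ECM regions; cells are labels >= 2.
"""

import numpy as np
from numba import njit

MEDIUM = 0
EPI = 1
PRE = 2
ECM = 3

MEDIUM_LABEL = 0
ECM_LABEL = 1

# 26 Moore-neighbourhood offsets and the 13 "positive" half-offsets used to
# enumerate each unordered voxel pair exactly once.
_offsets = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if not (dx == 0 and dy == 0 and dz == 0)],
    dtype=np.int64,
)
_half_offsets = _offsets[: len(_offsets) // 2].copy()


def _build_adjacency_masks() -> np.ndarray:
    """Bit i of _ADJ[j] is set when positions i and j of the 3×3×3 cube are
    Moore-adjacent (centre position 13 excluded from all masks)."""
    masks = np.zeros(27, np.int64)
    pos = [(i // 9, (i // 3) % 3, i % 3) for i in range(27)]
    for j in range(27):
        if j == 13:
            continue
        m = 0
        for i in range(27):
            if i == j or i == 13:
                continue
            if all(abs(a - b) <= 1 for a, b in zip(pos[i], pos[j])):
                m |= 1 << i
        masks[j] = m
    return masks


_ADJ = _build_adjacency_masks()


@njit(cache=True)
def hamiltonian_kernel(lab, typ, vol, tgt, J, kappa, eps):
    """Total energy: contact + volume-constraint + per-ECM-voxel cost."""
    nx, ny, nz = lab.shape
    E = 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                l1 = lab[x, y, z]
                t1 = typ[l1]
                for k in range(_half_offsets.shape[0]):
                    xx = x + _half_offsets[k, 0]
                    yy = y + _half_offsets[k, 1]
                    zz = z + _half_offsets[k, 2]
                    if xx < 0 or yy < 0 or zz < 0 or xx >= nx or yy >= ny or zz >= nz:
                        continue
                    l2 = lab[xx, yy, zz]
                    if l1 != l2:
                        E += J[t1, typ[l2]]
    for l in range(typ.shape[0]):
        if typ[l] == EPI or typ[l] == PRE:
            d = vol[l] - tgt[l]
            E += 0.5 * kappa * d * d
    E += eps * vol[ECM_LABEL]
    return E


@njit(cache=True)
def delta_energy_kernel(lab, typ, vol, tgt, J, kappa, eps, x, y, z, new_label):
    """Energy change of flipping voxel (x,y,z) to ``new_label``."""
    nx, ny, nz = lab.shape
    old = lab[x, y, z]
    told = typ[old]
    tnew = typ[new_label]
    dE = 0.0
    for k in range(_offsets.shape[0]):
        xx = x + _offsets[k, 0]
        yy = y + _offsets[k, 1]
        zz = z + _offsets[k, 2]
        if xx < 0 or yy < 0 or zz < 0 or xx >= nx or yy >= ny or zz >= nz:
            continue
        nl = lab[xx, yy, zz]
        tn = typ[nl]
        if nl != new_label:
            dE += J[tnew, tn]
        if nl != old:
            dE -= J[told, tn]
    if told == EPI or told == PRE:
        d = vol[old] - tgt[old]
        dE += 0.5 * kappa * ((d - 1.0) * (d - 1.0) - d * d)
    if tnew == EPI or tnew == PRE:
        d = vol[new_label] - tgt[new_label]
        dE += 0.5 * kappa * ((d + 1.0) * (d + 1.0) - d * d)
    if tnew == ECM:
        dE += eps
    if told == ECM:
        dE -= eps
    return dE


@njit(cache=True)
def locally_connected(lab, x, y, z, label):
    """Simple-point test: would removing (x,y,z) keep ``label`` connected?

    Sufficient condition — the same-label voxels of the 26-neighbourhood must
    form one Moore-connected component among themselves (centre excluded).
    Implemented as a bitmask closure over precomputed adjacency masks.
    """
    m = 0
    bit = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                if not (dx == 0 and dy == 0 and dz == 0):
                    if lab[x + dx, y + dy, z + dz] == label:
                        m |= 1 << bit
                bit += 1
    if m == 0:
        return False
    # seed with the lowest set bit, expand until fixed point
    reached = m & (-m)
    while True:
        grown = reached
        probe = reached
        while probe != 0:
            b = probe & (-probe)
            i = 0
            bb = b
            while bb > 1:
                bb >>= 1
                i += 1
            grown |= _ADJ[i] & m
            probe ^= b
        if grown == reached:
            break
        reached = grown
    return reached == m


@njit(cache=True, fastmath=True, inline="always")
def _delta_energy_interior(lab, typ, vol, tgt, J, kappa, eps, x, y, z,
                           new_label):
    """ΔE for a strictly interior voxel (no bounds checks)."""
    old = lab[x, y, z]
    told = typ[old]
    tnew = typ[new_label]
    dE = 0.0
    for k in range(_offsets.shape[0]):
        nl = lab[x + _offsets[k, 0], y + _offsets[k, 1], z + _offsets[k, 2]]
        tn = typ[nl]
        if nl != new_label:
            dE += J[tnew, tn]
        if nl != old:
            dE -= J[told, tn]
    if told == EPI or told == PRE:
        d = vol[old] - tgt[old]
        dE += kappa * (0.5 - d)
    if tnew == EPI or tnew == PRE:
        d = vol[new_label] - tgt[new_label]
        dE += kappa * (0.5 + d)
    if tnew == ECM:
        dE += eps
    if told == ECM:
        dE -= eps
    return dE


@njit(cache=True, fastmath=True)
def step_kernel(lab, typ, vol, tgt, J, alpha, phi, kappa, eps, kT, dt,
                ecm_enabled, seed):
    """One tau-leap sweep of length dt over the current boundary voxels.

    Boundary voxels are visited in random order; for each, one candidate
    target label is drawn uniformly from the distinct Moore-neighbour labels
    (plus the ECM label when a cell voxel touches a foreign PrE cell) and the
    copy is executed with probability 1 − exp(−λ·dt).  Moves that would empty
    or locally disconnect an EPI/PrE cell are rejected.  Returns the number of
    executed flips.
    """
    np.random.seed(seed)
    nx, ny, nz = lab.shape
    log_alpha = np.empty(4)
    for t in range(4):
        log_alpha[t] = np.log(alpha[t]) if alpha[t] > 0 else -np.inf
    idx = np.empty(nx * ny * nz, np.int64)
    nb = 0
    for x in range(1, nx - 1):
        for y in range(1, ny - 1):
            for z in range(1, nz - 1):
                l = lab[x, y, z]
                boundary = False
                for k in range(_offsets.shape[0]):
                    if lab[x + _offsets[k, 0], y + _offsets[k, 1],
                           z + _offsets[k, 2]] != l:
                        boundary = True
                        break
                if boundary:
                    idx[nb] = (x * ny + y) * nz + z
                    nb += 1
    # Fisher–Yates shuffle of the visit order
    for i in range(nb - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = idx[i]
        idx[i] = idx[j]
        idx[j] = tmp

    cand = np.empty(27, np.int64)
    n_flips = 0
    for q in range(nb):
        f = idx[q]
        z = f % nz
        y = (f // nz) % ny
        x = f // (ny * nz)
        l = lab[x, y, z]
        tl = typ[l]
        ncand = 0
        has_foreign_pre = False
        for k in range(_offsets.shape[0]):
            nl = lab[x + _offsets[k, 0], y + _offsets[k, 1], z + _offsets[k, 2]]
            if nl != l:
                if typ[nl] == PRE:
                    has_foreign_pre = True
                fresh = True
                for c in range(ncand):
                    if cand[c] == nl:
                        fresh = False
                        break
                if fresh:
                    cand[ncand] = nl
                    ncand += 1
        if ncand == 0:
            continue
        if ecm_enabled and (tl == EPI or tl == PRE) and has_foreign_pre:
            fresh = True
            for c in range(ncand):
                if cand[c] == ECM_LABEL:
                    fresh = False
                    break
            if fresh:
                cand[ncand] = ECM_LABEL
                ncand += 1
        nl = cand[np.random.randint(0, ncand)]
        tn = typ[nl]
        if alpha[tn] <= 0.0:
            continue
        dE = _delta_energy_interior(lab, typ, vol, tgt, J, kappa, eps,
                                    x, y, z, nl)
        loglam = log_alpha[tn] + phi[tl, tn] + min(0.0, -dE / kT)
        if loglam > 30.0:
            p = 1.0
        else:
            p = -np.expm1(-np.exp(loglam) * dt)
        if np.random.random() < p:
            if tl == EPI or tl == PRE:
                if vol[l] <= 1:
                    continue
                if not locally_connected(lab, x, y, z, l):
                    continue
            lab[x, y, z] = nl
            vol[l] -= 1
            vol[nl] += 1
            n_flips += 1
    return n_flips
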