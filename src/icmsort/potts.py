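"""3D Poissonian cellular Potts model of an isolated inner cell mass.

Cells (epiblast, EPI; primitive endoderm, PrE) are Moore-connected voxel
domains on a 1 μm³ lattice, evolving by label-copy events drawn as a Poisson
process so that the simulation carries physical time.  The energy is

    E = Σ_ij J_ij / 2  +  (κ/2) Σ_c (V_c − V̄_c)²  +  ε · N_ECM,

with contact coefficients J by voxel-type pair over Moore-neighbour voxel
pairs of differing label, a volume constraint on cells only (no perimeter
constraint — the cortex sets cell area on these timescales), and a per-voxel
energy cost ε on the extracellular-matrix (ECM) region driving its decay.
A copy of source type s over target type t fires at rate

    λ = α(t) · exp(φ(s, t)) · min(1, exp(−ΔE / k_B T)),

with per-type kinetic action rates α and active exponents φ (non-zero only
for cell→ECM copies, which models active deposition of matrix by PrE cells
at cell–cell contacts).  Cells grow linearly in preferred volume and divide
perpendicular to the principal axis of their gyration tensor when V̄ reaches
a target sampled from an empirical mitotic-volume distribution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from . import _kernels
from ._kernels import ECM_LABEL, MEDIUM_LABEL


class CellType(IntEnum):
    MEDIUM = _kernels.MEDIUM
    EPI = _kernels.EPI
    PRE = _kernels.PRE
    ECM = _kernels.ECM


_MOORE = np.ones((3, 3, 3), dtype=bool)

#: Empirical mitotic cell volumes (μm³) used as the division-target pool.
DIVISION_VOLUMES = (
    2406.63, 2428.09, 2455.23, 2517.92, 2994.28,
    3002.65, 3110.31, 3116.73, 3294.93, 4133.67,
)

#: Default contact energies (k_BT per Moore voxel-pair contact) encoding the
#: interfacial-tension ordering γ_PrE:M < γ_PrE:PrE < γ_EPI:EPI < γ_PrE:EPI
#: < γ_EPI:M.  ECM coefficients mirror PrE as in the model definition:
#: J_M:ECM = J_M:PrE, J_EPI:ECM = J_EPI:PrE, J_PrE:ECM = J_PrE:PrE.
DEFAULT_J = {
    (CellType.PRE, CellType.MEDIUM): 2.0,
    (CellType.PRE, CellType.PRE): 4.0,
    (CellType.EPI, CellType.EPI): 5.0,
    (CellType.EPI, CellType.PRE): 7.0,
    (CellType.EPI, CellType.MEDIUM): 14.0,
    (CellType.MEDIUM, CellType.MEDIUM): 0.0,
    (CellType.ECM, CellType.MEDIUM): 2.0,
    (CellType.ECM, CellType.EPI): 7.0,
    (CellType.ECM, CellType.PRE): 4.0,
    (CellType.ECM, CellType.ECM): 0.0,
}

#: Active exponent promoting cell→ECM copies.  Converting a cell voxel to
#: matrix creates ~15 fresh ECM:cell interfaces, so deposition carries an
#: intrinsic contact cost of tens of k_BT; the default exponent largely (not
#: fully) offsets it, keeping deposition frequent at contact corners while
#: avoiding a lattice-flooding saturated regime.
DEFAULT_PHI_ECM = 52.0


def _j_matrix(J: Mapping) -> np.ndarray:
    M = np.full((4, 4), np.nan)
    for (a, b), v in J.items():
        a, b = int(a), int(b)
        if not np.isnan(M[a, b]) and M[a, b] != v:
            raise ValueError(
                f"J table must be symmetric: conflicting entries for "
                f"({CellType(a).name}, {CellType(b).name})")
        M[a, b] = v
        M[b, a] = v
    return M


@dataclass
class SimParams:
    """All constants of the Potts simulation (energies in k_BT units)."""

    J: Mapping = field(default_factory=lambda: dict(DEFAULT_J))
    kappa: float = 1.0                      # volume stiffness, k_BT·μm⁻⁶
    alpha: Mapping | float = 16.0           # kinetic action rate, events·min⁻¹
    phi: Mapping | None = None              # active exponents φ(source, target)
    epsilon: float = 2.0                    # per-ECM-voxel cost, k_BT
    kT: float = 1.0
    dt: float = 0.1                         # integration step, min
    growth_rate: float = 2.0                # g, μm³·min⁻¹
    division_volumes: Sequence[float] = DIVISION_VOLUMES
    ecm_enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        Jm = _j_matrix(self.J)
        present = ~np.isnan(Jm)
        if not np.array_equal(Jm[present], Jm.T[present]):
            raise ValueError("J table must be symmetric")
        jm_pre = Jm[CellType.MEDIUM, CellType.PRE]
        jm_epi = Jm[CellType.MEDIUM, CellType.EPI]
        # equality permitted for symmetric (all-equal-tension) controls
        if np.isfinite(jm_pre) and np.isfinite(jm_epi) and jm_pre > jm_epi:
            raise ValueError(
                "tension ordering requires J_medium:PrE <= J_medium:EPI")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(np.asarray(self.alpha_array()) < 0):
            raise ValueError("alpha must be non-negative")
        dv = np.asarray(self.division_volumes, float)
        if dv.size == 0 or np.any(dv <= 0):
            raise ValueError("division_volumes must be non-empty and positive")

    def j_matrix(self) -> np.ndarray:
        return _j_matrix(self.J)

    def alpha_array(self) -> np.ndarray:
        if isinstance(self.alpha, Mapping):
            a = np.zeros(4)
            for t, v in self.alpha.items():
                a[int(t)] = v
            return a
        return np.full(4, float(self.alpha))

    def phi_matrix(self) -> np.ndarray:
        M = np.zeros((4, 4))
        phi = self.phi
        if phi is None:
            phi = {
                (CellType.EPI, CellType.ECM): DEFAULT_PHI_ECM,
                (CellType.PRE, CellType.ECM): DEFAULT_PHI_ECM,
            }
        for (s, t), v in phi.items():
            M[int(s), int(t)] = v
        return M

    def param_hash(self) -> str:
        payload = json.dumps({
            "J": sorted((int(a), int(b), float(v)) for (a, b), v in self.J.items()),
            "kappa": self.kappa,
            "alpha": list(self.alpha_array()),
            "phi": self.phi_matrix().tolist(),
            "epsilon": self.epsilon, "kT": self.kT, "dt": self.dt,
            "growth_rate": self.growth_rate,
            "division_volumes": list(map(float, self.division_volumes)),
            "ecm_enabled": self.ecm_enabled,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class VoxelLattice:
    """Label grid plus the per-cell registry (type, V, V̄, birth time).

    Labels 0 and 1 are the medium and ECM regions; cells carry labels >= 2.
    One voxel is 1 μm³.
    """

    def __init__(self, labels: np.ndarray, cell_types: np.ndarray,
                 target_volumes: np.ndarray | None = None,
                 birth_times: np.ndarray | None = None,
                 division_targets: np.ndarray | None = None):
        self.labels = np.ascontiguousarray(labels, dtype=np.int32)
        self.cell_types = np.asarray(cell_types, dtype=np.int16)
        n = self.cell_types.shape[0]
        self.volumes = np.bincount(self.labels.ravel(), minlength=n).astype(np.int64)
        if self.labels.max() >= n:
            raise ValueError("grid contains labels missing from the registry")
        self.target_volumes = (np.asarray(target_volumes, float).copy()
                               if target_volumes is not None
                               else self.volumes.astype(float))
        self.base_volumes = self.target_volumes.copy()   # V̄_c(0)
        self.birth_times = (np.asarray(birth_times, float).copy()
                            if birth_times is not None else np.zeros(n))
        self.division_targets = (np.asarray(division_targets, float).copy()
                                 if division_targets is not None
                                 else np.full(n, np.inf))

    # -- registry views -------------------------------------------------
    @property
    def shape(self):
        return self.labels.shape

    def cell_ids(self, types=(CellType.EPI, CellType.PRE)) -> np.ndarray:
        mask = np.isin(self.cell_types, [int(t) for t in types])
        mask &= self.volumes > 0
        return np.flatnonzero(mask)

    @property
    def cell_registry(self) -> dict:
        reg = {}
        for l in range(self.cell_types.shape[0]):
            if self.volumes[l] > 0 or self.cell_types[l] in (CellType.EPI, CellType.PRE):
                reg[int(l)] = {
                    "type": CellType(int(self.cell_types[l])),
                    "V": int(self.volumes[l]),
                    "V_target": float(self.target_volumes[l]),
                    "birth_time": float(self.birth_times[l]),
                }
        return reg

    def recount_volumes(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(),
                           minlength=self.cell_types.shape[0]).astype(np.int64)

    def centroids(self) -> dict[int, np.ndarray]:
        """Cell-ID → centroid (μm) for all live EPI/PrE cells."""
        ids = self.cell_ids()
        if ids.size == 0:
            return {}
        coms = ndimage.center_of_mass(np.ones(self.shape), self.labels, ids)
        return {int(l): np.asarray(c, float) for l, c in zip(ids, coms)}

    def connected(self, label: int) -> bool:
        mask = self.labels == label
        if not mask.any():
            return False
        _, n = ndimage.label(mask, structure=_MOORE)
        return n == 1

    def check_connectivity(self) -> bool:
        return all(self.connected(int(l)) for l in self.cell_ids())

    def copy(self) -> "VoxelLattice":
        out = VoxelLattice(self.labels.copy(), self.cell_types.copy(),
                           self.target_volumes, self.birth_times,
                           self.division_targets)
        out.base_volumes = self.base_volumes.copy()
        return out

    def _grow_registry(self, new_type: CellType) -> int:
        """Append a fresh label and return it."""
        self.cell_types = np.append(self.cell_types, np.int16(int(new_type)))
        self.volumes = np.append(self.volumes, np.int64(0))
        self.target_volumes = np.append(self.target_volumes, 0.0)
        self.base_volumes = np.append(self.base_volumes, 0.0)
        self.birth_times = np.append(self.birth_times, 0.0)
        self.division_targets = np.append(self.division_targets, np.inf)
        return self.cell_types.shape[0] - 1


@dataclass
class SimTrace:
    """Recorded simulation outputs (times in min, distances in μm)."""

    times: list = field(default_factory=list)
    sorting_scores: list = field(default_factory=list)
    ecm_radial_histograms: list = field(default_factory=list)
    ecm_mean_radius: list = field(default_factory=list)
    cell_centroids: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for s in self.sorting_scores:
            if s is not None and not -1.0 <= s <= 1.0:
                raise ValueError("sorting scores must lie in [-1, 1]")

    def as_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_min": self.times,
            "sorting_score": self.sorting_scores,
            "ecm_mean_radius_um": self.ecm_mean_radius,
        })


# ---------------------------------------------------------------------------
# Energy and kinetics


def hamiltonian(lattice: VoxelLattice, params: SimParams) -> float:
    """Total configuration energy in k_BT."""
    J = params.j_matrix()
    present = np.unique(lattice.cell_types[np.unique(lattice.labels)])
    for a in present:
        for b in present:
            if np.isnan(J[a, b]):
                raise ValueError(
                    f"missing J entry for type pair ({CellType(int(a)).name}, "
                    f"{CellType(int(b)).name})")
    return float(_kernels.hamiltonian_kernel(
        lattice.labels, lattice.cell_types, lattice.volumes,
        lattice.target_volumes, np.nan_to_num(J), params.kappa, params.epsilon))


def delta_energy(lattice: VoxelLattice, params: SimParams,
                 voxel: tuple[int, int, int], new_label: int) -> float:
    """Incremental ΔE of copying ``new_label`` onto ``voxel``."""
    x, y, z = voxel
    return float(_kernels.delta_energy_kernel(
        lattice.labels, lattice.cell_types, lattice.volumes,
        lattice.target_volumes, np.nan_to_num(params.j_matrix()),
        params.kappa, params.epsilon, x, y, z, int(new_label)))


def transition_rate(deltaE: float, source_type: CellType, target_type: CellType,
                    params: SimParams) -> float:
    """Poisson rate λ = α(target) · e^φ(source,target) · min(1, e^(−ΔE/kT)).

    Computed in log space; saturating exponents (e.g. the default φ for ECM
    deposition) yield ``inf``, which downstream maps to execution probability
    1 per step.
    """
    a = params.alpha_array()[int(target_type)]
    if a == 0.0:
        return 0.0
    phi = params.phi_matrix()[int(source_type), int(target_type)]
    with np.errstate(over="ignore"):
        boost = float(np.exp(phi))
        accept = min(1.0, float(np.exp(-deltaE / params.kT)))
    return a * boost * accept


def apply_flip(lattice: VoxelLattice, voxel: tuple[int, int, int],
               new_label: int) -> None:
    """Execute a label copy, maintaining the volume bookkeeping."""
    x, y, z = voxel
    old = lattice.labels[x, y, z]
    lattice.labels[x, y, z] = new_label
    lattice.volumes[old] -= 1
    lattice.volumes[new_label] += 1


def simulate_step(lattice: VoxelLattice, params: SimParams,
                  rng: np.random.Generator) -> VoxelLattice:
    """One tau-leap step of length dt (in place; the lattice is returned)."""
    seed = int(rng.integers(0, 2**31 - 1))
    _kernels.step_kernel(
        lattice.labels, lattice.cell_types, lattice.volumes,
        lattice.target_volumes, np.nan_to_num(params.j_matrix()),
        params.alpha_array(), params.phi_matrix(), params.kappa,
        params.epsilon, params.kT, params.dt, params.ecm_enabled, seed)
    return lattice


# ---------------------------------------------------------------------------
# Growth and division


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Largest-eigenvalue axis of the gyration tensor, with the documented
    tie-break (x-axis / lexicographically first basis vector) when the tensor
    is degenerate."""
    X = coords - coords.mean(axis=0)
    G = X.T @ X / len(coords)
    w, V = np.linalg.eigh(G)
    if w[-1] - w[0] < 1e-9 * max(w[-1], 1.0):
        return np.array([1.0, 0.0, 0.0])
    axis = V[:, -1]
    # canonical orientation: first non-zero component positive
    for c in axis:
        if abs(c) > 1e-12:
            if c < 0:
                axis = -axis
            break
    return axis


def divide_cell(lattice: VoxelLattice, label: int, t: float,
                params: SimParams, rng: np.random.Generator) -> int:
    """Split ``label`` by the plane through its centroid perpendicular to the
    principal gyration axis.  Returns the new daughter's label.

    Daughter V̄ is initialised to the actual post-split volume and fresh
    division targets are resampled with replacement from the empirical pool.
    Stray fragments produced by the discrete plane cut are reassigned so both
    daughters stay Moore-connected.
    """
    coords = np.argwhere(lattice.labels == label)
    axis = _principal_axis(coords)
    proj = (coords - coords.mean(axis=0)) @ axis
    side_b = proj > 0
    if side_b.all() or not side_b.any():
        side_b = proj > np.median(proj)
        if side_b.all() or not side_b.any():     # all projections identical
            side_b = np.zeros(len(coords), bool)
            side_b[: len(coords) // 2] = True
    new_label = lattice._grow_registry(CellType(int(lattice.cell_types[label])))
    b_idx = coords[side_b]
    lattice.labels[b_idx[:, 0], b_idx[:, 1], b_idx[:, 2]] = new_label

    # repair connectivity: minority components of either daughter flip sides
    for _ in range(8):
        moved = False
        for lbl, other in ((label, new_label), (new_label, label)):
            mask = lattice.labels == lbl
            comp, n = ndimage.label(mask, structure=_MOORE)
            if n <= 1:
                continue
            sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            lattice.labels[(comp > 0) & (comp != keep)] = other
            moved = True
        if not moved:
            break

    for lbl in (label, new_label):
        v = int((lattice.labels == lbl).sum())
        lattice.volumes[lbl] = v
        lattice.target_volumes[lbl] = float(v)
        lattice.base_volumes[lbl] = float(v)
        lattice.birth_times[lbl] = t
        lattice.division_targets[lbl] = float(
            rng.choice(np.asarray(params.division_volumes, float)))
    return new_label


def grow_and_divide(lattice: VoxelLattice, params: SimParams, t: float,
                    rng: np.random.Generator) -> VoxelLattice:
    """Linear preferred-volume growth V̄(t) = V̄(0) + g·(t − t_birth), with
    division once V̄ reaches the cell's sampled target volume."""
    g = params.growth_rate
    for label in lattice.cell_ids():
        label = int(label)
        vbar = lattice.base_volumes[label] + g * (t - lattice.birth_times[label])
        if g > 0 and vbar >= lattice.division_targets[label] and lattice.volumes[label] >= 2:
            divide_cell(lattice, label, t, params, rng)
        else:
            lattice.target_volumes[label] = vbar
    return lattice


# ---------------------------------------------------------------------------
# Initialisation and driver


def init_icm(n_cells: int, pre_fraction: float, radius: float,
             params: SimParams | None = None, seed: int = 0,
             margin: int = 3) -> VoxelLattice:
    """Voronoi-seeded spherical aggregate with a salt-and-pepper fate pattern.

    Exactly ``round(pre_fraction * n_cells)`` cells are typed PrE, assigned
    spatially at random.  The box has a one-voxel frozen medium shell.
    """
    if not 0 <= pre_fraction <= 1:
        raise ValueError("pre_fraction must lie in [0, 1]")
    if n_cells < 1:
        raise ValueError("need at least one cell")
    sphere_vol = 4.0 / 3.0 * np.pi * radius**3
    if sphere_vol < 30 * n_cells:
        raise ValueError(
            f"radius {radius} μm cannot pack {n_cells} cells at a workable "
            "mean cell volume (≥30 μm³ each)")
    rng = np.random.default_rng(seed)
    L = int(2 * (radius + margin)) + 2
    c = (L - 1) / 2.0
    grid = np.indices((L, L, L)).reshape(3, -1).T.astype(float)
    r2 = ((grid - c) ** 2).sum(axis=1)
    inside = r2 <= radius**2

    # farthest-point sampling of n_cells seeds from a random pool → even,
    # deterministic packing
    pool = grid[inside]
    pool = pool[rng.permutation(len(pool))]
    seeds = [pool[0]]
    d2 = ((pool - seeds[0]) ** 2).sum(axis=1)
    for _ in range(n_cells - 1):
        k = int(np.argmax(d2))
        seeds.append(pool[k])
        d2 = np.minimum(d2, ((pool - pool[k]) ** 2).sum(axis=1))
    seeds = np.asarray(seeds)

    labels = np.zeros((L, L, L), np.int32)
    dist = ((pool[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(dist, axis=1) + 2
    flat = labels.reshape(-1)
    flat[np.flatnonzero(inside)] = assign

    types = np.zeros(n_cells + 2, np.int16)
    types[ECM_LABEL] = int(CellType.ECM)
    n_pre = int(round(pre_fraction * n_cells))
    pre_ids = rng.choice(n_cells, size=n_pre, replace=False) + 2
    types[2:] = int(CellType.EPI)
    types[pre_ids] = int(CellType.PRE)

    lat = VoxelLattice(labels, types)
    # repair rare discretisation-induced fragments: strays join an adjacent cell
    for _ in range(6):
        fixed = True
        for label in lat.cell_ids():
            label = int(label)
            mask = lat.labels == label
            comp, n = ndimage.label(mask, structure=_MOORE)
            if n <= 1:
                continue
            fixed = False
            sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            for ci in range(1, n + 1):
                if ci == keep:
                    continue
                frag = comp == ci
                dil = ndimage.binary_dilation(frag, structure=_MOORE) & ~frag
                neigh = lat.labels[dil]
                neigh = neigh[neigh >= 2]
                if neigh.size:
                    lat.labels[frag] = np.bincount(neigh).argmax()
                else:
                    lat.labels[frag] = MEDIUM_LABEL
        if fixed:
            break
    lat.volumes = lat.recount_volumes()
    lat.target_volumes = lat.volumes.astype(float)
    lat.base_volumes = lat.target_volumes.copy()
    if params is not None:
        dv = np.asarray(params.division_volumes, float)
        lat.division_targets = np.where(
            np.isin(lat.cell_types, (int(CellType.EPI), int(CellType.PRE))),
            rng.choice(dv, size=lat.cell_types.shape[0]), np.inf)
    return lat


def _sorting_score_from_lattice(lattice: VoxelLattice) -> float | None:
    from .tracks import sorting_score
    cents = lattice.centroids()
    if not cents:
        return None
    ids = sorted(cents)
    pos = np.array([cents[i] for i in ids])
    fates = np.array(["PRE" if lattice.cell_types[i] == CellType.PRE else "EPI"
                      for i in ids])
    if len(set(fates)) < 2:
        return None
    r = np.linalg.norm(pos - pos.mean(axis=0), axis=1)
    return sorting_score(r, fates)


def _ecm_distances(lattice: VoxelLattice) -> np.ndarray | None:
    """ECM-voxel distances (μm) to the cell-aggregate centroid."""
    cell_mask = np.isin(lattice.cell_types[lattice.labels],
                        (int(CellType.EPI), int(CellType.PRE)))
    ecm_mask = lattice.labels == ECM_LABEL
    if not ecm_mask.any() or not cell_mask.any():
        return None
    centroid = np.argwhere(cell_mask).mean(axis=0)
    return np.linalg.norm(np.argwhere(ecm_mask) - centroid, axis=1)


def ecm_radial_histogram(lattice: VoxelLattice, bin_width: float = 1.0):
    """Instantaneous histogram of ECM-voxel distance from the aggregate
    centroid (``None`` when no ECM exists)."""
    d = _ecm_distances(lattice)
    if d is None:
        return None, np.nan
    edges = np.arange(0, d.max() + 2 * bin_width, bin_width)
    hist, _ = np.histogram(d, bins=edges)
    return (hist, edges), float(d.mean())


def run(params: SimParams, init: VoxelLattice, duration: float,
        record_every: float, snapshot_every: float | None = None,
        ecm_sample_every: float = 1.0) -> SimTrace:
    """Advance the simulation for ``duration`` minutes, recording the sorting
    score, the ECM radial histogram and cell centroids every ``record_every``
    minutes (the initial state is always recorded).

    The ECM radial statistic of a record point pools voxel distances sampled
    every ``ecm_sample_every`` minutes over the preceding window, which
    averages out snapshot noise in the (small, rapidly turning-over) ECM
    population; the recorded histogram is the pooled distance histogram.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    lattice = init
    rng = np.random.default_rng(params.seed)
    trace = SimTrace(meta={"seed": params.seed,
                           "param_hash": params.param_hash(),
                           "dt": params.dt})
    pooled: list[np.ndarray] = []

    def sample_ecm():
        d = _ecm_distances(lattice)
        if d is not None:
            pooled.append(d)

    def record(t):
        trace.times.append(t)
        trace.sorting_scores.append(_sorting_score_from_lattice(lattice))
        if pooled:
            d = np.concatenate(pooled)
            edges = np.arange(0, d.max() + 2.0, 1.0)
            trace.ecm_radial_histograms.append(np.histogram(d, bins=edges))
            trace.ecm_mean_radius.append(float(d.mean()))
        else:
            trace.ecm_radial_histograms.append(None)
            trace.ecm_mean_radius.append(np.nan)
        pooled.clear()
        trace.cell_centroids.append(lattice.centroids())
        if snapshot_every is not None and (
                t == 0 or round(t / snapshot_every, 9) % 1 == 0):
            trace.snapshots.append((t, lattice.labels.copy()))

    sample_ecm()
    record(0.0)
    n_steps = int(round(duration / params.dt))
    rec_stride = max(1, int(round(record_every / params.dt)))
    samp_stride = max(1, int(round(ecm_sample_every / params.dt)))
    for k in range(1, n_steps + 1):
        t = k * params.dt
        simulate_step(lattice, params, rng)
        if params.growth_rate > 0:
            grow_and_divide(lattice, params, t, rng)
        if k % samp_stride == 0:
            sample_ecm()
        if k % rec_stride == 0 or k == n_steps:
            record(t)
    return trace


# ---------------------------------------------------------------------------
# Snapshot I/O: multi-plane TIFF label stacks + JSON sidecar


def save_snapshot(lattice: VoxelLattice, path: str | Path) -> None:
    """Write the label grid as a 16-bit multi-plane TIFF (one image per
    z-plane) with a JSON sidecar mapping labels to types."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, lattice.labels.astype(np.uint16),
                     photometric="minisblack")
    sidecar = {
        str(l): CellType(int(t)).name
        for l, t in enumerate(lattice.cell_types)
        if lattice.volumes[l] > 0
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_snapshot(path: str | Path) -> VoxelLattice:
    import tifffile

    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    n = max(int(k) for k in sidecar) + 1
    types = np.zeros(max(n, 2), np.int16)
    types[ECM_LABEL] = int(CellType.ECM)
    for k, name in sidecar.items():
        types[int(k)] = int(CellType[name])
    return VoxelLattice(labels, types)
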