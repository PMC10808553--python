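"""Exhaustive lattice docking of B-cell receptor peptides around an antigen.

A BCR of length L is folded as a self-avoiding walk on the molecular lattice
around a rigid antigen chain. Every conformation (pose) touching the antigen
with at least ``min_contacts`` non-covalent adjacencies is enumerated once;
each pose is reduced to its sequence-independent *contact profile* — the
list of (BCR index, antigen residue) inter-molecular contacts plus the
(i, j) intra-BCR contacts with |i-j| >= 2. Scoring a candidate sequence is
then a table-lookup sum per profile:

    E = sum_inter U(seq[i], antigen_res) + s * sum_intra U(seq[i], seq[j])

and the binding energy is the minimum over all profiles. Energies (kT) map
to unitless affinities via Aff = exp((Emax - E)/C) with Emax = -100 and
C = 2.8 by default, so Aff = 1 at E = Emax and stronger binding (lower E)
gives higher affinity. Many geometric poses share one contact profile
(dangling tails do not change the contacts), so profiles are deduplicated
during enumeration; the representative pose of a profile is the first one
encountered in the fixed enumeration order, which makes optimal-pose
tie-breaking deterministic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence, Union

import numpy as np
from numba import njit
from scipy.ndimage import distance_transform_cdt

from .lattice import AMINO_ACIDS, LatticeChain, UNIT_STEPS, residues_to_indices

if TYPE_CHECKING:  # pragma: no cover
    from .antigens import Antigen

__all__ = [
    "AffinityParams",
    "BindingResult",
    "PoseSet",
    "Docker",
    "enumerate_poses",
    "binding_energy",
    "profile_energy",
    "energy_to_affinity",
    "affinity_to_energy",
]

_STEPS = np.array(UNIT_STEPS, dtype=np.int64)


# ---------------------------------------------------------------------------
# Energy <-> affinity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffinityParams:
    """Parameters of the energy-to-affinity map.

    mode="strength" (default) returns exp((emax - E)/C): affinity 1 at
    E = emax, in (0, 1) for weaker binders and above 1 for stronger ones.
    mode="literal" returns exp((E - emax)/C), the printed-formula sign.
    """

    emax: float = -100.0
    c: float = 2.8
    mode: str = "strength"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"affinity scale C must be positive, got {self.c}")
        if self.mode not in ("strength", "literal"):
            raise ValueError(f"unknown affinity mode {self.mode!r}")


def energy_to_affinity(energy, params: AffinityParams = AffinityParams()):
    """Convert binding energy (kT) to unitless affinity."""
    e = np.asarray(energy, dtype=np.float64)
    if params.mode == "strength":
        out = np.exp((params.emax - e) / params.c)
    else:
        out = np.exp((e - params.emax) / params.c)
    return float(out) if np.isscalar(energy) or out.ndim == 0 else out


def affinity_to_energy(aff, params: AffinityParams = AffinityParams()):
    """Exact inverse of :func:`energy_to_affinity` in the active mode."""
    a = np.asarray(aff, dtype=np.float64)
    if np.any(a <= 0):
        raise ValueError("affinity must be positive")
    if params.mode == "strength":
        out = params.emax - params.c * np.log(a)
    else:
        out = params.emax + params.c * np.log(a)
    return float(out) if np.isscalar(aff) or out.ndim == 0 else out


@dataclass(frozen=True)
class BindingResult:
    """Optimal binding energy of a sequence against one antigen."""

    energy: float        # kT, minimum over all enumerated poses
    affinity: float      # energy_to_affinity(energy)
    pose_id: int         # index of the optimal pose in enumeration order


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

_FNV_OFFSET1 = np.uint64(0xCBF29CE484222325)
_FNV_OFFSET2 = np.uint64(0x84222325CBF29CE4)
_FNV_PRIME = np.uint64(0x100000001B3)


@njit(cache=True)
def _enumerate_kernel(antigen_grid, node_grid, dist_grid, L, min_contacts,
                      max_poses, table_cap, entry_cap,
                      used, key1, key2, rep_pose, mult,
                      inter_start, inter_len, intra_start, intra_len,
                      inter_buf, intra_buf, rep_sx, rep_moves):
    """Depth-first enumeration of all valid poses with in-flight profile
    deduplication via an open-addressing hash table.

    Returns (status, n_poses, n_slots, inter_cursor, intra_cursor) where
    status is 0=ok, 1=hash table full (retry bigger), 2=entry buffer full
    (retry bigger), 3=pose cap exceeded.
    """
    nx, ny, nz = antigen_grid.shape
    mask = np.uint64(table_cap - 1)
    n_poses = 0
    n_slots = 0
    ic = 0  # inter buffer cursor
    jc = 0  # intra buffer cursor

    px = np.empty(L, dtype=np.int64)
    py = np.empty(L, dtype=np.int64)
    pz = np.empty(L, dtype=np.int64)
    dstack = np.empty(L, dtype=np.int64)
    mtaken = np.empty(L, dtype=np.int64)
    ccum = np.empty(L, dtype=np.int64)
    inter_codes = np.empty(6 * L, dtype=np.uint16)
    intra_codes = np.empty(6 * L, dtype=np.uint16)
    dxs = np.array([1, -1, 0, 0, 0, 0], dtype=np.int64)
    dys = np.array([0, 0, 1, -1, 0, 0], dtype=np.int64)
    dzs = np.array([0, 0, 0, 0, 1, -1], dtype=np.int64)

    for sx in range(1, nx - 1):
        for sy in range(1, ny - 1):
            for sz in range(1, nz - 1):
                if antigen_grid[sx, sy, sz]:
                    continue
                d0 = dist_grid[sx, sy, sz]
                if d0 > L - 1:
                    continue
                # contacts made by the start residue
                c0 = 0
                for k in range(6):
                    if antigen_grid[sx + dxs[k], sy + dys[k], sz + dzs[k]]:
                        c0 += 1
                px[0] = sx; py[0] = sy; pz[0] = sz
                ccum[0] = c0
                depth = 0
                dstack[0] = 0
                while depth >= 0:
                    if depth == L - 1:
                        # complete pose: check contacts, record profile
                        if ccum[depth] >= min_contacts:
                            if n_poses >= max_poses:
                                return 3, n_poses, n_slots, ic, jc
                            # collect inter and intra contact codes
                            ni = 0
                            nj = 0
                            for i in range(L):
                                xi = px[i]; yi = py[i]; zi = pz[i]
                                for k in range(6):
                                    qx = xi + dxs[k]; qy = yi + dys[k]; qz = zi + dzs[k]
                                    if antigen_grid[qx, qy, qz]:
                                        inter_codes[ni] = np.uint16((i << 8) | node_grid[qx, qy, qz])
                                        ni += 1
                                for j in range(i - 1):
                                    dd = abs(xi - px[j]) + abs(yi - py[j]) + abs(zi - pz[j])
                                    if dd == 1:
                                        intra_codes[nj] = np.uint16((i << 8) | j)
                                        nj += 1
                            # canonical order: insertion sort (short arrays)
                            for a in range(1, ni):
                                v = inter_codes[a]
                                b = a - 1
                                while b >= 0 and inter_codes[b] > v:
                                    inter_codes[b + 1] = inter_codes[b]
                                    b -= 1
                                inter_codes[b + 1] = v
                            for a in range(1, nj):
                                v = intra_codes[a]
                                b = a - 1
                                while b >= 0 and intra_codes[b] > v:
                                    intra_codes[b + 1] = intra_codes[b]
                                    b -= 1
                                intra_codes[b + 1] = v
                            # 128-bit FNV-1a style hash
                            h1 = _FNV_OFFSET1
                            h2 = _FNV_OFFSET2
                            for a in range(ni):
                                h1 = (h1 ^ np.uint64(inter_codes[a])) * _FNV_PRIME
                                h2 = (h2 ^ np.uint64(inter_codes[a] + 7919)) * _FNV_PRIME
                            h1 = (h1 ^ np.uint64(0xFFFF)) * _FNV_PRIME
                            h2 = (h2 ^ np.uint64(0xABCD)) * _FNV_PRIME
                            for a in range(nj):
                                h1 = (h1 ^ np.uint64(intra_codes[a])) * _FNV_PRIME
                                h2 = (h2 ^ np.uint64(intra_codes[a] + 104729)) * _FNV_PRIME
                            slot = np.int64(h1 & mask)
                            while True:
                                if not used[slot]:
                                    if n_slots * 10 >= table_cap * 7:
                                        return 1, n_poses, n_slots, ic, jc
                                    if ic + ni > entry_cap or jc + nj > entry_cap:
                                        return 2, n_poses, n_slots, ic, jc
                                    used[slot] = 1
                                    key1[slot] = np.int64(h1)
                                    key2[slot] = np.int64(h2)
                                    rep_pose[slot] = n_poses
                                    mult[slot] = 1
                                    inter_start[slot] = ic
                                    inter_len[slot] = ni
                                    intra_start[slot] = jc
                                    intra_len[slot] = nj
                                    for a in range(ni):
                                        inter_buf[ic + a] = inter_codes[a]
                                    for a in range(nj):
                                        intra_buf[jc + a] = intra_codes[a]
                                    ic += ni
                                    jc += nj
                                    rep_sx[slot, 0] = px[0]
                                    rep_sx[slot, 1] = py[0]
                                    rep_sx[slot, 2] = pz[0]
                                    for a in range(L - 1):
                                        rep_moves[slot, a] = mtaken[a]
                                    n_slots += 1
                                    break
                                elif key1[slot] == np.int64(h1) and key2[slot] == np.int64(h2):
                                    mult[slot] += 1
                                    break
                                slot = (slot + 1) & np.int64(mask)
                            n_poses += 1
                        # backtrack
                        depth -= 1
                        continue
                    # try next direction at this depth
                    k = dstack[depth]
                    moved = False
                    while k < 6:
                        qx = px[depth] + dxs[k]
                        qy = py[depth] + dys[k]
                        qz = pz[depth] + dzs[k]
                        k += 1
                        if qx < 1 or qx >= nx - 1 or qy < 1 or qy >= ny - 1 or qz < 1 or qz >= nz - 1:
                            continue
                        if antigen_grid[qx, qy, qz]:
                            continue
                        clash = False
                        for j in range(depth + 1):
                            if px[j] == qx and py[j] == qy and pz[j] == qz:
                                clash = True
                                break
                        if clash:
                            continue
                        # contacts made by this residue
                        cq = 0
                        for kk in range(6):
                            if antigen_grid[qx + dxs[kk], qy + dys[kk], qz + dzs[kk]]:
                                cq += 1
                        ctot = ccum[depth] + cq
                        # admissible bound on future contacts
                        rem = L - 1 - (depth + 1)
                        d = dist_grid[qx, qy, qz]
                        avail = rem - (d - 1 if d > 1 else 0)
                        if avail < 0:
                            avail = 0
                        if ctot + 5 * avail < min_contacts:
                            continue
                        dstack[depth] = k
                        mtaken[depth] = k - 1
                        depth += 1
                        px[depth] = qx; py[depth] = qy; pz[depth] = qz
                        ccum[depth] = ctot
                        dstack[depth] = 0
                        moved = True
                        break
                    if not moved:
                        depth -= 1
    return 0, n_poses, n_slots, ic, jc


@njit(cache=True)
def _score_min(seq, agres, inter_ptr, inter_buf, intra_ptr, intra_buf, U, s):
    """Minimum energy over all profiles for one sequence; first-index
    tie-break (profiles are ordered by representative pose index)."""
    n = inter_ptr.shape[0] - 1
    best_e = np.inf
    best_p = -1
    for p in range(n):
        e = 0.0
        for a in range(inter_ptr[p], inter_ptr[p + 1]):
            code = inter_buf[a]
            e += U[seq[code >> 8], agres[code & 0xFF]]
        ei = 0.0
        for a in range(intra_ptr[p], intra_ptr[p + 1]):
            code = intra_buf[a]
            ei += U[seq[code >> 8], seq[code & 0xFF]]
        e += s * ei
        if e < best_e:
            best_e = e
            best_p = p
    return best_e, best_p


@njit(cache=True)
def _score_min_batch(seqs, agres, inter_ptr, inter_buf, intra_ptr, intra_buf, U, s):
    ns = seqs.shape[0]
    energies = np.empty(ns, dtype=np.float64)
    poses = np.empty(ns, dtype=np.int64)
    for i in range(ns):
        e, p = _score_min(seqs[i], agres, inter_ptr, inter_buf, intra_ptr, intra_buf, U, s)
        energies[i] = e
        poses[i] = p
    return energies, poses


@njit(cache=True)
def _score_all(seq, agres, inter_ptr, inter_buf, intra_ptr, intra_buf, U, s):
    """Energy of every profile for one sequence (diagnostics / tests)."""
    n = inter_ptr.shape[0] - 1
    out = np.empty(n, dtype=np.float64)
    for p in range(n):
        e = 0.0
        for a in range(inter_ptr[p], inter_ptr[p + 1]):
            code = inter_buf[a]
            e += U[seq[code >> 8], agres[code & 0xFF]]
        ei = 0.0
        for a in range(intra_ptr[p], intra_ptr[p + 1]):
            code = intra_buf[a]
            ei += U[seq[code >> 8], seq[code & 0xFF]]
        out[p] = e + s * ei
    return out


# ---------------------------------------------------------------------------
# PoseSet
# ---------------------------------------------------------------------------

@dataclass
class PoseSet:
    """Deduplicated contact profiles of all binding poses of a length-L BCR
    around one antigen, ordered by representative pose index."""

    structure_key: str           # hash of antigen geometry + (L, min_contacts)
    L: int
    min_contacts: int
    n_poses: int                 # raw geometric pose count
    inter_ptr: np.ndarray        # int64 (n_profiles+1,)
    inter_buf: np.ndarray        # uint16 codes (bcr_index << 8) | antigen_node_index
    intra_ptr: np.ndarray
    intra_buf: np.ndarray        # uint16 codes (i << 8) | j, j <= i-2
    rep_pose: np.ndarray         # int64, representative raw pose index
    multiplicity: np.ndarray     # int64, geometric poses per profile
    rep_start: np.ndarray        # int64 (n_profiles, 3), lattice frame of antigen
    rep_moves: np.ndarray        # int8 (n_profiles, L-1), direction codes

    @property
    def n_profiles(self) -> int:
        return len(self.inter_ptr) - 1

    def __len__(self) -> int:
        return self.n_profiles

    def profile_positions(self, p: int) -> np.ndarray:
        """Decode the representative pose of profile p into lattice coords."""
        pos = np.empty((self.L, 3), dtype=np.int64)
        pos[0] = self.rep_start[p]
        for k in range(self.L - 1):
            pos[k + 1] = pos[k] + _STEPS[self.rep_moves[p, k]]
        return pos

    def profile_contacts(self, p: int) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        inter = [(int(c) >> 8, int(c) & 0xFF)
                 for c in self.inter_buf[self.inter_ptr[p]:self.inter_ptr[p + 1]]]
        intra = [(int(c) >> 8, int(c) & 0xFF)
                 for c in self.intra_buf[self.intra_ptr[p]:self.intra_ptr[p + 1]]]
        return inter, intra


def _antigen_chain(antigen) -> LatticeChain:
    return antigen.structure if hasattr(antigen, "structure") else antigen


def antigen_key(antigen, L: int = None, min_contacts: int = None) -> str:
    """Stable hash over antigen geometry + residues (and docking params)."""
    chain = _antigen_chain(antigen)
    h = hashlib.sha1()
    for (x, y, z), r in zip(chain.positions, chain.residues):
        h.update(f"{x},{y},{z},{r};".encode())
    if L is not None:
        h.update(f"L={L};mc={min_contacts}".encode())
    return h.hexdigest()[:16]


def structure_key(antigen, L: int, min_contacts: int) -> str:
    """Hash of antigen geometry only (contact profiles are residue-agnostic:
    inter contacts store antigen *node indices*, so one pose set serves every
    residue assignment of the same structure)."""
    chain = _antigen_chain(antigen)
    h = hashlib.sha1()
    for x, y, z in chain.positions:
        h.update(f"{x},{y},{z};".encode())
    h.update(f"L={L};mc={min_contacts}".encode())
    return h.hexdigest()[:16]


def enumerate_poses(antigen, L: int, min_contacts: int = 1,
                    max_poses: int = 50_000_000) -> PoseSet:
    """Enumerate every binding conformation of a length-L BCR around the
    antigen with at least ``min_contacts`` BCR-antigen adjacencies, reduced
    to deduplicated contact profiles.

    Enumeration order is fixed (starts lexicographic, then directions
    +x,-x,+y,-y,+z,-z depth-first), so pose indices are deterministic. The
    result depends only on (antigen, L, min_contacts) and is safe to cache.
    """
    chain = _antigen_chain(antigen)
    if len(chain) == 0:
        raise ValueError("antigen is empty")
    if L < 2:
        raise ValueError(f"BCR length must be >= 2, got {L}")
    if min_contacts < 1:
        raise ValueError(f"min_contacts must be >= 1, got {min_contacts}")
    if len(chain) > 255:
        raise ValueError("antigens longer than 255 residues are not supported "
                         "by the uint16 contact coding")

    coords = chain.coords
    lo = coords.min(axis=0) - (L + 1)
    hi = coords.max(axis=0) + (L + 1)
    shape = tuple(hi - lo + 1)
    antigen_grid = np.zeros(shape, dtype=np.uint8)
    node_grid = np.full(shape, -1, dtype=np.int16)
    for node_i, (x, y, z) in enumerate(coords - lo):
        antigen_grid[x, y, z] = 1
        node_grid[x, y, z] = node_i

    # taxicab distance from each free node to the nearest contact-shell node
    # (free node adjacent to the antigen); admissible lower bound for pruning
    shell = np.zeros(shape, dtype=bool)
    for dx, dy, dz in UNIT_STEPS:
        shell |= np.roll(antigen_grid.astype(bool), (dx, dy, dz), axis=(0, 1, 2))
    shell &= ~antigen_grid.astype(bool)
    dist_grid = distance_transform_cdt(~shell, metric="taxicab").astype(np.int64)

    table_cap = 1 << 16
    entry_cap = 1 << 20
    while True:
        used = np.zeros(table_cap, dtype=np.uint8)
        key1 = np.zeros(table_cap, dtype=np.int64)
        key2 = np.zeros(table_cap, dtype=np.int64)
        rep_pose = np.zeros(table_cap, dtype=np.int64)
        mult = np.zeros(table_cap, dtype=np.int64)
        inter_start = np.zeros(table_cap, dtype=np.int64)
        inter_len = np.zeros(table_cap, dtype=np.int64)
        intra_start = np.zeros(table_cap, dtype=np.int64)
        intra_len = np.zeros(table_cap, dtype=np.int64)
        inter_buf = np.zeros(entry_cap, dtype=np.uint16)
        intra_buf = np.zeros(entry_cap, dtype=np.uint16)
        rep_sx = np.zeros((table_cap, 3), dtype=np.int64)
        rep_moves = np.zeros((table_cap, max(L - 1, 1)), dtype=np.int8)
        status, n_poses, n_slots, ic, jc = _enumerate_kernel(
            antigen_grid, node_grid, dist_grid, L, min_contacts,
            max_poses, table_cap, entry_cap,
            used, key1, key2, rep_pose, mult,
            inter_start, inter_len, intra_start, intra_len,
            inter_buf, intra_buf, rep_sx, rep_moves)
        if status == 0:
            break
        if status == 1:
            table_cap *= 2
        elif status == 2:
            entry_cap *= 2
        else:
            raise MemoryError(
                f"pose enumeration exceeded the cap of {max_poses} poses for "
                f"antigen of {len(chain)} residues at L={L}, "
                f"min_contacts={min_contacts}; raise max_poses or "
                f"min_contacts, or use a smaller antigen")

    occ = np.flatnonzero(used)
    order = occ[np.argsort(rep_pose[occ], kind="stable")]
    n_prof = len(order)
    inter_ptr = np.zeros(n_prof + 1, dtype=np.int64)
    intra_ptr = np.zeros(n_prof + 1, dtype=np.int64)
    np.cumsum(inter_len[order], out=inter_ptr[1:])
    np.cumsum(intra_len[order], out=intra_ptr[1:])
    inter_out = np.empty(inter_ptr[-1], dtype=np.uint16)
    intra_out = np.empty(intra_ptr[-1], dtype=np.uint16)
    for i, slot in enumerate(order):
        inter_out[inter_ptr[i]:inter_ptr[i + 1]] = \
            inter_buf[inter_start[slot]:inter_start[slot] + inter_len[slot]]
        intra_out[intra_ptr[i]:intra_ptr[i + 1]] = \
            intra_buf[intra_start[slot]:intra_start[slot] + intra_len[slot]]

    return PoseSet(
        structure_key=structure_key(antigen, L, min_contacts),
        L=L,
        min_contacts=min_contacts,
        n_poses=int(n_poses),
        inter_ptr=inter_ptr,
        inter_buf=inter_out,
        intra_ptr=intra_ptr,
        intra_buf=intra_out,
        rep_pose=rep_pose[order] ,
        multiplicity=mult[order],
        rep_start=rep_sx[order] + lo,
        rep_moves=rep_moves[order],
    )


def profile_energy(seq: str, profile_index: int, pose_set: PoseSet, antigen,
                   potential, s: float = 1.0) -> float:
    """Energy of one sequence in one specific contact profile."""
    if len(seq) != pose_set.L:
        raise ValueError(f"sequence length {len(seq)} != pose set L {pose_set.L}")
    sidx = residues_to_indices(seq)
    agres = residues_to_indices(_antigen_chain(antigen).residues)
    U = potential.reindexed(AMINO_ACIDS)
    inter, intra = pose_set.profile_contacts(profile_index)
    e = sum(U[sidx[i], agres[node]] for i, node in inter)
    e += s * sum(U[sidx[i], sidx[j]] for i, j in intra)
    return float(e)


# ---------------------------------------------------------------------------
# Docker: potential + params + pose-set cache
# ---------------------------------------------------------------------------

class Docker:
    """Binds a contact potential and affinity parameters to a reusable
    pose-set cache, the per-sequence evaluation surface used by the GC
    simulation."""

    def __init__(self, potential, L: int = 9, min_contacts: int = 1,
                 stabilization: float = 1.0,
                 affinity_params: AffinityParams = AffinityParams(),
                 max_poses: int = 50_000_000):
        self.potential = potential
        self.U = np.ascontiguousarray(potential.reindexed(AMINO_ACIDS))
        self.L = L
        self.min_contacts = min_contacts
        self.stabilization = float(stabilization)
        self.affinity_params = affinity_params
        self.max_poses = max_poses
        self._cache: dict[str, PoseSet] = {}

    def pose_set(self, antigen) -> PoseSet:
        # keyed by geometry only: the same structure with reassigned
        # residues reuses the enumeration (contacts store node indices)
        key = structure_key(antigen, self.L, self.min_contacts)
        ps = self._cache.get(key)
        if ps is None:
            ps = enumerate_poses(antigen, self.L, self.min_contacts, self.max_poses)
            self._cache[key] = ps
        return ps

    def attach_pose_set(self, antigen, pose_set: PoseSet) -> None:
        """Install a precomputed pose set (e.g. loaded from a cache file)."""
        expected = structure_key(antigen, self.L, self.min_contacts)
        if pose_set.structure_key != expected:
            raise ValueError("pose set does not match this antigen / docking parameters")
        self._cache[expected] = pose_set

    @staticmethod
    def _agres(antigen) -> np.ndarray:
        return residues_to_indices(_antigen_chain(antigen).residues)

    def binding_energy(self, seq: str, antigen) -> BindingResult:
        ps = self.pose_set(antigen)
        if ps.n_profiles == 0:
            raise ValueError(
                f"antigen unbindable at min_contacts={self.min_contacts}: "
                "no valid pose exists")
        if len(seq) != self.L:
            raise ValueError(f"sequence length {len(seq)} != configured L {self.L}")
        sidx = residues_to_indices(seq)
        e, p = _score_min(sidx, self._agres(antigen), ps.inter_ptr, ps.inter_buf,
                          ps.intra_ptr, ps.intra_buf, self.U, self.stabilization)
        return BindingResult(energy=float(e),
                             affinity=energy_to_affinity(e, self.affinity_params),
                             pose_id=int(ps.rep_pose[p]))

    def batch_energies(self, seqs: Sequence[str], antigen) -> np.ndarray:
        """Optimal energies for many sequences against one antigen."""
        ps = self.pose_set(antigen)
        if ps.n_profiles == 0:
            raise ValueError(
                f"antigen unbindable at min_contacts={self.min_contacts}")
        mat = np.stack([residues_to_indices(s) for s in seqs])
        e, _ = _score_min_batch(mat, self._agres(antigen), ps.inter_ptr,
                                ps.inter_buf, ps.intra_ptr, ps.intra_buf,
                                self.U, self.stabilization)
        return e

    def batch_binding(self, seqs: Sequence[str], antigen) -> tuple[np.ndarray, np.ndarray]:
        """(energies, optimal profile indices) for many sequences."""
        ps = self.pose_set(antigen)
        mat = np.stack([residues_to_indices(s) for s in seqs])
        return _score_min_batch(mat, self._agres(antigen), ps.inter_ptr,
                                ps.inter_buf, ps.intra_ptr, ps.intra_buf,
                                self.U, self.stabilization)

    def affinity(self, seq: str, antigen) -> float:
        return self.binding_energy(seq, antigen).affinity


def binding_energy(seq: str, antigen, potential, L: Optional[int] = None,
                   min_contacts: int = 1, stabilization: float = 1.0,
                   affinity_params: AffinityParams = AffinityParams()) -> BindingResult:
    """One-shot optimal binding energy (convenience wrapper; use
    :class:`Docker` when evaluating many sequences against one antigen)."""
    L = L if L is not None else len(seq)
    d = Docker(potential, L=L, min_contacts=min_contacts,
               stabilization=stabilization, affinity_params=affinity_params)
    return d.binding_energy(seq, antigen)


# ---------------------------------------------------------------------------
# Pose-set cache files (npz, versioned, keyed by antigen hash + params)
# ---------------------------------------------------------------------------

_CACHE_VERSION = 1


def save_pose_set(ps: PoseSet, path) -> None:
    np.savez_compressed(
        path, version=_CACHE_VERSION, structure_key=ps.structure_key, L=ps.L,
        min_contacts=ps.min_contacts, n_poses=ps.n_poses,
        inter_ptr=ps.inter_ptr, inter_buf=ps.inter_buf,
        intra_ptr=ps.intra_ptr, intra_buf=ps.intra_buf,
        rep_pose=ps.rep_pose, multiplicity=ps.multiplicity,
        rep_start=ps.rep_start, rep_moves=ps.rep_moves)


def load_pose_set(path) -> PoseSet:
    with np.load(path, allow_pickle=False) as z:
        if int(z["version"]) != _CACHE_VERSION:
            raise ValueError(f"pose-set cache {path} has unsupported version {z['version']}")
        return PoseSet(
            structure_key=str(z["structure_key"]), L=int(z["L"]),
            min_contacts=int(z["min_contacts"]), n_poses=int(z["n_poses"]),
            inter_ptr=z["inter_ptr"], inter_buf=z["inter_buf"],
            intra_ptr=z["intra_ptr"], intra_buf=z["intra_buf"],
            rep_pose=z["rep_pose"], multiplicity=z["multiplicity"],
            rep_start=z["rep_start"], rep_moves=z["rep_moves"])
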