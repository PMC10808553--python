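"""The agent-based germinal-center simulation.

The GC is a sphere of 5-um lattice nodes split into a dark zone (DZ, lower
hemisphere) and light zone (LZ, upper hemisphere). Tfh cells and FDCs are
placed randomly in the LZ, stromal cells in the DZ; antigen is spread
uniformly over FDC dendrite nodes, equally per domain. Founder B cells flow
in at 2 cells/h (Poisson), proliferate ``founder_divisions`` times in the DZ
mutating their BCR at each division, then compete in the LZ: capture of
antigen units on dendrite nodes (probability min(1, Aff) per check, floor
1e-8, always targeting the highest-affinity stocked domain), apoptosis if
nothing is captured within the search time, then Tfh selection (only the
adjacent B cell with the most internalized antigen accrues polarization;
0.5 h within a 3 h window selects). Selected cells recycle to the DZ with a
pMHC-dependent division number (Hill in captured units) and antigen shared
asymmetrically in 72% of divisions; daughters ending their divisions with
antigen become output cells, the rest re-enter LZ competition. Output cells
differentiate into antibody-secreting cells with a 24 h half-life, each
secreting 3e-8 mol/h.

Event order within a step is fixed: influx -> movement -> DZ cycling and
division -> capture (on its own cadence) and search resolution -> Tfh
signaling and selection/apoptosis -> output/ASC bookkeeping. Every source of
randomness draws from its own seeded stream, so a (config, antigen set,
founder pool, seed) tuple fully determines the run. An integer antigen
ledger (units on FDCs + units inside live B cells + units removed with dead
and output cells = total) is maintained exactly and can be audited at any
step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .antigens import AntigenSet
from .config import GCConfig
from .docking import Docker, energy_to_affinity
from .lattice import UNIT_STEPS
from .potential import load_potential
from .repertoire import FounderPool, mutate

__all__ = ["GCState", "SimulationResult", "initialize", "step", "run",
           "run_replicates", "divisions_from_antigen", "draw_cycle_times"]

_STEPS = np.array(UNIT_STEPS, dtype=np.int64)

# B cell states
CB = 0          # centroblast: cycling/dividing, DZ-homing
UNSEL = 1       # unselected centrocyte: LZ antigen search
TFH = 2         # in the Tfh selection window
_GC_STATES = (CB, UNSEL, TFH)


def divisions_from_antigen(a: int, nmin: int = 1, nmax: int = 6,
                           k: float = 9.0, h: float = 2.0) -> int:
    """pMHC-dependent number of divisions granted at selection: a Hill
    function of internalized antigen units, Nmin at a=0 saturating to Nmax."""
    if a < 0:
        raise ValueError("antigen units must be >= 0")
    if a == 0:
        return int(nmin)
    x = float(a) ** h
    return int(nmin + round((nmax - nmin) * x / (x + k ** h)))


class _BCells:
    """Struct-of-arrays B-cell registry with slot reuse."""

    _FIELDS = dict(pos=(np.int64, 3), state=(np.int8, None),
                   a=(np.int64, None), div_left=(np.int16, None),
                   cycle_t=(np.float64, None), search_t=(np.float64, None),
                   window_t=(np.float64, None), polar_t=(np.float64, None),
                   mut=(np.int32, None), seq_id=(np.int64, None),
                   founder_dom=(np.int16, None),
                   contact_t=(np.float64, None), contact_tfh=(np.int64, None))

    def __init__(self, capacity: int = 1024):
        self.capacity = capacity
        self.alive = np.zeros(capacity, dtype=bool)
        for name, (dt, width) in self._FIELDS.items():
            shape = (capacity,) if width is None else (capacity, width)
            setattr(self, name, np.zeros(shape, dtype=dt))
        self._free: list[int] = list(range(capacity - 1, -1, -1))

    def _grow(self) -> None:
        old = self.capacity
        self.capacity = old * 2
        self.alive = np.concatenate([self.alive, np.zeros(old, dtype=bool)])
        for name, (dt, width) in self._FIELDS.items():
            arr = getattr(self, name)
            pad_shape = (old,) if width is None else (old, width)
            setattr(self, name, np.concatenate([arr, np.zeros(pad_shape, dtype=dt)]))
        self._free.extend(range(2 * old - 1, old - 1, -1))

    def new(self) -> int:
        if not self._free:
            self._grow()
        i = self._free.pop()
        self.alive[i] = True
        return i

    def kill(self, i: int) -> None:
        self.alive[i] = False
        self._free.append(i)

    def indices(self, state: Optional[int] = None) -> np.ndarray:
        if state is None:
            return np.flatnonzero(self.alive)
        return np.flatnonzero(self.alive & (self.state == state))

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())


class _SeqRegistry:
    """Unique BCR sequences with cached per-domain optimal energies."""

    def __init__(self, docker: Docker, antigens: AntigenSet):
        self.docker = docker
        self.antigens = antigens
        self.seqs: list[str] = []
        self._ids: dict[str, int] = {}
        self.energies = np.zeros((0, antigens.n_domains))

    def register(self, seq: str) -> int:
        sid = self._ids.get(seq)
        if sid is not None:
            return sid
        sid = len(self.seqs)
        self.seqs.append(seq)
        self._ids[seq] = sid
        e = np.array([self.docker.binding_energy(seq, ag).energy
                      for ag in self.antigens.domains])
        self.energies = np.vstack([self.energies, e[None, :]])
        return sid

    def register_batch(self, seqs: list[str]) -> np.ndarray:
        new = [s for s in dict.fromkeys(seqs) if s not in self._ids]
        if new:
            block = np.stack([self.docker.batch_energies(new, ag)
                              for ag in self.antigens.domains], axis=1)
            for s in new:
                self._ids[s] = len(self.seqs)
                self.seqs.append(s)
            self.energies = np.vstack([self.energies, block])
        return np.array([self._ids[s] for s in seqs], dtype=np.int64)

    def affinities(self, seq_ids: np.ndarray) -> np.ndarray:
        return energy_to_affinity(self.energies[seq_ids],
                                  self.docker.affinity_params)


@dataclass
class GCState:
    config: GCConfig
    antigens: AntigenSet
    docker: Docker
    registry: _SeqRegistry
    time_h: float
    step_index: int
    # geometry
    inside: np.ndarray            # bool grid: node within the GC sphere
    is_lz: np.ndarray             # bool grid: upper hemisphere
    occ: np.ndarray               # int64 grid: -1 free, >=0 B id, -2 stroma/soma, 1e6+i Tfh
    dend_idx: np.ndarray          # int64 grid: dendrite node index or -1
    node_antigen: np.ndarray      # (n_dend_nodes, K) int64 units
    field_lz: np.ndarray          # chemokine guidance toward LZ (CXCL13-like)
    field_dz: np.ndarray          # chemokine guidance toward DZ (CXCL12-like)
    # agents
    bcells: _BCells
    tfh_pos: np.ndarray           # (n_tfh, 3)
    tfh_dir: np.ndarray
    tfh_busy: np.ndarray = None   # type: ignore  # B id the Tfh is engaged with, -1 free
    bcell_dir: np.ndarray = None  # type: ignore  # per-slot walk direction
    # founder pool
    founders: list = field(default_factory=list)   # [(domain index, seq_id)]
    # ledger & outputs
    antigen_removed_dead: int = 0
    antigen_removed_output: int = 0
    outputs: list = field(default_factory=list)    # (t, seq_id, mut, dom, a)
    n_outputs: int = 0
    output_pool: float = 0.0      # output cells not yet differentiated
    asc: float = 0.0              # antibody-secreting cells
    antibody_mol: float = 0.0
    # rng streams
    rngs: dict = field(default_factory=dict)
    # movement precomputations
    off6: np.ndarray = None          # type: ignore  # flat offsets of the 6 steps
    nb_logit: dict = field(default_factory=dict)     # per-direction field values

    # ---- derived helpers -------------------------------------------------
    def antigen_on_fdc(self) -> int:
        return int(self.node_antigen.sum())

    def antigen_in_cells(self) -> int:
        return int(self.bcells.a[self.bcells.alive].sum())

    def ledger_balance(self) -> dict:
        """Exact integer antigen audit; 'total' must equal antigen_total."""
        on_fdc = self.antigen_on_fdc()
        in_cells = self.antigen_in_cells()
        return {"on_fdc": on_fdc, "in_cells": in_cells,
                "removed_dead": self.antigen_removed_dead,
                "removed_output": self.antigen_removed_output,
                "total": on_fdc + in_cells + self.antigen_removed_dead
                         + self.antigen_removed_output}

    def alive_affinities(self) -> np.ndarray:
        """(n_alive, K) affinity of every living GC B cell to each domain."""
        ids = self.bcells.seq_id[self.bcells.indices()]
        return self.registry.affinities(ids)


def _relax_field(sources: np.ndarray, inside: np.ndarray,
                 n_iter: int = 150) -> np.ndarray:
    """Steady-state chemokine guidance field: Jacobi relaxation of the
    diffusion equation with fixed unit sources, zero outside the sphere."""
    f = np.zeros(sources.shape, dtype=np.float64)
    src = sources.astype(bool)
    for _ in range(n_iter):
        acc = np.zeros_like(f)
        for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
            acc += np.roll(f, shift, axis=ax)
        f = acc / 6.0
        f[~inside] = 0.0
        f[src] = 1.0
    return f


def _random_free_node(state: GCState, rng: np.random.Generator,
                      lz: Optional[bool] = None, tries: int = 200) -> Optional[tuple]:
    D = state.occ.shape[0]
    for _ in range(tries):
        p = tuple(rng.integers(0, D, size=3))
        if not state.inside[p] or state.occ[p] != -1:
            continue
        if lz is True and not state.is_lz[p]:
            continue
        if lz is False and state.is_lz[p]:
            continue
        return p
    return None


def initialize(config: GCConfig, antigen_set: AntigenSet,
               founder_pool: FounderPool, docker: Optional[Docker] = None,
               seed: Optional[int] = None) -> GCState:
    """Build the initial GC: stroma placed, antigen loaded on dendrites,
    chemokine fields precomputed, founder sequences registered."""
    seed = config.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(8)
    names = ["placement", "influx", "movement", "shm", "capture", "cycle",
             "tfh", "misc"]
    rngs = {n: np.random.default_rng(s) for n, s in zip(names, streams)}

    if docker is None:
        docker = Docker(load_potential(), L=config.bcr_length,
                        min_contacts=config.min_contacts,
                        stabilization=config.stabilization,
                        affinity_params=config.affinity_params,
                        max_poses=config.max_poses)

    R = config.radius_nodes
    D = 2 * R + 3          # one-node pad so neighbor lookups never leave the grid
    ax = np.arange(D) - (R + 1)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = xx ** 2 + yy ** 2 + zz ** 2 <= R ** 2
    is_lz = zz >= 0

    occ = np.full((D, D, D), -1, dtype=np.int64)
    occ[~inside] = -9      # sentinel: never free, never a cell
    dend_idx = np.full((D, D, D), -1, dtype=np.int64)
    rng = rngs["placement"]

    state = GCState(config=config, antigens=antigen_set, docker=docker,
                    registry=_SeqRegistry(docker, antigen_set),
                    time_h=0.0, step_index=0, inside=inside, is_lz=is_lz,
                    occ=occ, dend_idx=dend_idx,
                    node_antigen=np.zeros((0, antigen_set.n_domains), dtype=np.int64),
                    field_lz=np.zeros((D, D, D)), field_dz=np.zeros((D, D, D)),
                    bcells=_BCells(), tfh_pos=np.zeros((config.n_tfh, 3), dtype=np.int64),
                    tfh_dir=rng.integers(6, size=config.n_tfh), rngs=rngs)
    state.tfh_busy = np.full(config.n_tfh, -1, dtype=np.int64)
    state.bcell_dir = np.zeros(state.bcells.capacity, dtype=np.int64)

    # FDC somas + dendrites in the LZ
    arm_nodes = int(round(config.arm_length_um / config.node_size_um))
    dend_nodes: list[tuple] = []
    arm_dirs = _STEPS[:config.fdc_arms]
    for _ in range(config.n_fdc):
        p = _random_free_node(state, rng, lz=True)
        if p is None:
            raise ValueError("could not place all FDCs: GC too crowded")
        occ[p] = -2
        for d in arm_dirs:
            for k in range(1, arm_nodes + 1):
                q = (p[0] + k * d[0], p[1] + k * d[1], p[2] + k * d[2])
                if not (0 <= q[0] < D and 0 <= q[1] < D and 0 <= q[2] < D):
                    break
                if not inside[q]:
                    break
                if dend_idx[q] == -1:
                    dend_idx[q] = len(dend_nodes)
                    dend_nodes.append(q)

    # Tfh in the LZ, stromal cells in the DZ
    for i in range(config.n_tfh):
        p = _random_free_node(state, rng, lz=True)
        if p is None:
            raise ValueError("could not place all Tfh cells: GC too crowded")
        occ[p] = 1_000_000 + i
        state.tfh_pos[i] = p
    for _ in range(config.n_stromal):
        p = _random_free_node(state, rng, lz=False)
        if p is None:
            raise ValueError("could not place all stromal cells: GC too crowded")
        occ[p] = -2

    # antigen: per-domain equal split, spread uniformly over dendrite nodes
    n_dend = len(dend_nodes)
    if n_dend == 0:
        raise ValueError("no FDC dendrite nodes: cannot distribute antigen")
    K = antigen_set.n_domains
    node_antigen = np.zeros((n_dend, K), dtype=np.int64)
    per_domain, dom_rem = divmod(config.antigen_total, K)
    for d in range(K):
        units = per_domain + (1 if d < dom_rem else 0)
        q, r = divmod(units, n_dend)
        node_antigen[:, d] = q
        node_antigen[:r, d] += 1
    state.node_antigen = node_antigen

    # chemokine guidance fields (static, precomputed), plus per-direction
    # neighbor views used by the movement kernel
    lz_src = dend_idx >= 0
    dz_src = (occ == -2) & ~is_lz
    state.field_lz = _relax_field(lz_src, inside)
    state.field_dz = _relax_field(dz_src, inside)
    state.off6 = np.array([(dx * D + dy) * D + dz for dx, dy, dz in UNIT_STEPS],
                          dtype=np.int64)
    flat_inside = inside.reshape(-1)
    state.nb_logit = {}
    for name, f in (("lz", state.field_lz), ("dz", state.field_dz)):
        flat = f.reshape(-1)
        nb = np.full((6, flat.size), -np.inf)
        idx = np.flatnonzero(flat_inside)
        for k in range(6):
            tgt = idx + state.off6[k]
            valid = flat_inside[tgt]
            nb[k, idx[valid]] = flat[tgt[valid]]
        state.nb_logit[name] = nb

    # founder pool: register sequences once, cache energies
    dom_index = {ag.identity: i for i, ag in enumerate(antigen_set.domains)}
    flat = founder_pool.all_sequences
    if not flat:
        raise ValueError("founder pool is empty")
    sids = state.registry.register_batch([s for _, s in flat])
    state.founders = [(dom_index[agid], int(sid))
                      for (agid, _), sid in zip(flat, sids)]
    return state


# ---------------------------------------------------------------------------
# per-step subroutines
# ---------------------------------------------------------------------------

def draw_cycle_times(config: GCConfig, rng: np.random.Generator,
                     n: int = 1) -> np.ndarray:
    """Cell-cycle durations ~ Normal(cycle_mean_h, cycle_sd_h) truncated to
    positive (invalid draws are redrawn)."""
    out = rng.normal(config.cycle_mean_h, config.cycle_sd_h, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(config.cycle_mean_h, config.cycle_sd_h,
                              size=int(bad.sum()))
        bad = out <= 0
    return out


def _draw_cycle(state: GCState, n: int = 1) -> np.ndarray:
    return draw_cycle_times(state.config, state.rngs["cycle"], n)


def _influx(state: GCState) -> None:
    cfg = state.config
    if state.time_h >= cfg.inflow_duration_h:
        return
    n_new = state.rngs["influx"].poisson(cfg.founder_influx_per_h * cfg.dt_h)
    for _ in range(n_new):
        p = _random_free_node(state, state.rngs["influx"])
        if p is None:
            continue  # GC completely full; founder bounces
        dom, sid = state.founders[state.rngs["influx"].integers(len(state.founders))]
        b = state.bcells.new()
        if b >= len(state.bcell_dir):
            state.bcell_dir = np.concatenate(
                [state.bcell_dir, np.zeros(len(state.bcell_dir), dtype=np.int64)])
        bc = state.bcells
        bc.pos[b] = p
        bc.state[b] = CB
        bc.a[b] = 0
        bc.div_left[b] = cfg.founder_divisions
        bc.cycle_t[b] = _draw_cycle(state, 1)[0]
        bc.search_t[b] = bc.window_t[b] = bc.polar_t[b] = 0.0
        bc.mut[b] = 0
        bc.seq_id[b] = sid
        bc.founder_dom[b] = dom
        bc.contact_t[b] = 0.0
        bc.contact_tfh[b] = -1
        state.bcell_dir[b] = state.rngs["influx"].integers(6)
        state.occ[p] = b


def _move_agents(state: GCState) -> None:
    """Persistent random walk with chemokine bias for B and Tfh cells.

    Each mobile agent moves with probability speed*dt/node_size; its walk
    direction is redrawn with probability dt/persistence from a softmax over
    the guidance-field gain of the six neighbor nodes. Moves into occupied
    or outside nodes fail (the direction is redrawn); simultaneous moves to
    one node are resolved in favor of a random one of the contenders.
    """
    cfg = state.config
    rng = state.rngs["movement"]
    D = state.occ.shape[0]
    occ_flat = state.occ.reshape(-1)
    bc = state.bcells

    b_idx = bc.indices()
    n_b = len(b_idx)
    n_t = len(state.tfh_pos)
    n = n_b + n_t
    if n == 0:
        return
    pos = np.vstack([bc.pos[b_idx], state.tfh_pos]) if n_b else state.tfh_pos.copy()
    flat = (pos[:, 0] * D + pos[:, 1]) * D + pos[:, 2]
    paired = np.zeros(n, dtype=bool)
    if n_b:
        paired[:n_b] = bc.contact_tfh[b_idx] >= 0
    paired[n_b:] = state.tfh_busy >= 0
    dirs = np.concatenate([state.bcell_dir[b_idx], state.tfh_dir]) if n_b \
        else state.tfh_dir.copy()

    # which guidance field each agent follows
    want_dz = np.zeros(n, dtype=bool)
    if n_b:
        want_dz[:n_b] = bc.state[b_idx] == CB   # DZ-homing; others LZ-homing

    p_move = min(1.0, cfg.speed_um_min * 60.0 * cfg.dt_h / cfg.node_size_um)
    p_turn = min(1.0, cfg.dt_h * 60.0 / cfg.persistence_min)
    moving = (rng.random(n) < p_move) & ~paired
    turning = (rng.random(n) < p_turn) & ~paired

    # redraw directions via Gumbel-softmax over neighbor field gains
    t_idx = np.flatnonzero(turning)
    if len(t_idx):
        logits = np.where(want_dz[t_idx, None],
                          state.nb_logit["dz"][:, flat[t_idx]].T,
                          state.nb_logit["lz"][:, flat[t_idx]].T)
        logits = cfg.chemo_weight * 100.0 * logits
        gumbel = -np.log(-np.log(rng.random(logits.shape) + 1e-300) + 1e-300)
        dirs[t_idx] = np.argmax(logits + gumbel, axis=1)

    m_idx = np.flatnonzero(moving)
    if len(m_idx):
        # synchronous update: targets must be free before the step; among
        # simultaneous movers to one node a random one wins, the rest turn
        tflat = flat[m_idx] + state.off6[dirs[m_idx]]
        ok = occ_flat[tflat] == -1
        cand = m_idx[ok]
        if len(cand):
            perm = rng.permutation(len(cand))
            shuffled = cand[perm]
            _, first = np.unique(tflat[ok][perm], return_index=True)
            winners = shuffled[first]
            wflat = flat[winners] + state.off6[dirs[winners]]
            occ_flat[flat[winners]] = -1
            wpos = np.empty((len(winners), 3), dtype=np.int64)
            wpos[:, 0], r = np.divmod(wflat, D * D)
            wpos[:, 1], wpos[:, 2] = np.divmod(r, D)
            is_b = winners < n_b
            if is_b.any():
                ids = b_idx[winners[is_b]]
                occ_flat[wflat[is_b]] = ids
                bc.pos[ids] = wpos[is_b]
            if (~is_b).any():
                tids = winners[~is_b] - n_b
                occ_flat[wflat[~is_b]] = 1_000_000 + tids
                state.tfh_pos[tids] = wpos[~is_b]
            lost = np.ones(len(m_idx), dtype=bool)
            lost[np.isin(m_idx, winners)] = False
        else:
            lost = np.ones(len(m_idx), dtype=bool)
        blocked = m_idx[lost]
        dirs[blocked] = rng.integers(6, size=len(blocked))  # blocked: turn
    if n_b:
        state.bcell_dir[b_idx] = dirs[:n_b]
        state.tfh_dir[:] = dirs[n_b:]
    else:
        state.tfh_dir[:] = dirs


def _finalize_divisions(state: GCState, b: int) -> None:
    """A cell that has completed its attributed divisions either leaves as an
    output cell (if it retained antigen) or returns to LZ competition."""
    bc = state.bcells
    if bc.a[b] > 0:
        state.antigen_removed_output += int(bc.a[b])
        state.outputs.append((state.time_h, int(bc.seq_id[b]), int(bc.mut[b]),
                              int(bc.founder_dom[b]), int(bc.a[b])))
        state.n_outputs += 1
        state.output_pool += 1.0
        state.occ[tuple(bc.pos[b])] = -1
        bc.kill(b)
    else:
        bc.state[b] = UNSEL
        bc.search_t[b] = 0.0


def _divide_cells(state: GCState) -> None:
    cfg = state.config
    bc = state.bcells
    cycling = bc.indices(CB)
    if len(cycling) == 0:
        return
    bc.cycle_t[cycling] -= cfg.dt_h
    due = cycling[bc.cycle_t[cycling] <= 0]
    if len(due) == 0:
        return
    rng = state.rngs["shm"]
    for b in due:
        # find a free neighbor for the daughter; else division waits
        free = []
        for d in _STEPS:
            q = (bc.pos[b][0] + d[0], bc.pos[b][1] + d[1], bc.pos[b][2] + d[2])
            if state.occ[q] == -1:
                free.append(q)
        if not free:
            bc.cycle_t[b] = 0.0  # retry next step
            continue
        q = free[rng.integers(len(free))]
        # antigen split: asymmetric (all to one daughter) or even
        a = int(bc.a[b])
        if rng.random() < cfg.asym_prob:
            a1, a2 = (a, 0) if rng.random() < 0.5 else (0, a)
        else:
            half, odd = divmod(a, 2)
            extra = int(odd and rng.random() < 0.5)
            a1, a2 = half + extra, a - half - extra
        parent_seq = state.registry.seqs[bc.seq_id[b]]
        s1, m1 = mutate(parent_seq, cfg.shm_p, rng)
        s2, m2 = mutate(parent_seq, cfg.shm_p, rng)
        sid1 = state.registry.register(s1)
        sid2 = state.registry.register(s2)
        nd = bc.div_left[b] - 1
        cyc = _draw_cycle(state, 2)
        # parent slot becomes daughter 1
        bc.a[b] = a1
        bc.seq_id[b] = sid1
        bc.mut[b] += m1
        bc.div_left[b] = nd
        bc.cycle_t[b] = cyc[0]
        # daughter 2 in the free neighbor node
        b2 = bc.new()
        if b2 >= len(state.bcell_dir):
            state.bcell_dir = np.concatenate(
                [state.bcell_dir, np.zeros(len(state.bcell_dir), dtype=np.int64)])
        bc.pos[b2] = q
        bc.state[b2] = CB
        bc.a[b2] = a2
        bc.div_left[b2] = nd
        bc.cycle_t[b2] = cyc[1]
        bc.search_t[b2] = bc.window_t[b2] = bc.polar_t[b2] = 0.0
        bc.mut[b2] = bc.mut[b] - m1 + m2
        bc.seq_id[b2] = sid2
        bc.founder_dom[b2] = bc.founder_dom[b]
        bc.contact_t[b2] = 0.0
        bc.contact_tfh[b2] = -1
        state.bcell_dir[b2] = rng.integers(6)
        state.occ[q] = b2
        if nd <= 0:
            _finalize_divisions(state, b)
            _finalize_divisions(state, b2)


def _capture_and_search(state: GCState, do_capture: bool) -> None:
    cfg = state.config
    bc = state.bcells
    searching = bc.indices(UNSEL)
    if len(searching) == 0:
        return
    if do_capture:
        rng = state.rngs["capture"]
        params = state.docker.affinity_params
        for b in searching:
            di = state.dend_idx[tuple(bc.pos[b])]
            if di < 0:
                continue
            stock = state.node_antigen[di]
            if stock.sum() == 0:
                continue
            affs = energy_to_affinity(state.registry.energies[bc.seq_id[b]], params)
            affs = np.where(stock > 0, affs, -np.inf)
            dom = int(np.argmax(affs))
            aff = affs[dom]
            if aff < cfg.capture_min_affinity:
                continue
            if rng.random() < min(1.0, cfg.capture_rate * aff):
                state.node_antigen[di, dom] -= 1
                bc.a[b] += 1
    bc.search_t[searching] += cfg.dt_h
    done = searching[bc.search_t[searching] >= cfg.search_time_h]
    for b in done:
        if bc.a[b] > 0:
            bc.state[b] = TFH
            bc.window_t[b] = 0.0
            bc.polar_t[b] = 0.0
            bc.contact_t[b] = 0.0
            bc.contact_tfh[b] = -1
        else:
            state.occ[tuple(bc.pos[b])] = -1
            bc.kill(b)   # apoptosis: failed to capture any antigen


def _tfh_selection(state: GCState) -> None:
    """Tfh help with explicit contacts: a free Tfh engages the adjacent
    selection-phase B cell with the most internalized antigen for a contact
    of fixed duration, during which both partners are immobile and the B
    cell accrues polarization time. Accrued polarization of 0.5 h within
    the 3 h window selects the cell; window expiry kills it."""
    cfg = state.config
    bc = state.bcells
    in_window = bc.indices(TFH)
    if len(in_window) == 0 and not (state.tfh_busy >= 0).any():
        return
    D = state.occ.shape[0]
    occ_flat = state.occ.reshape(-1)

    # ongoing contacts: accrue polarization, run down the contact clock
    engaged = np.flatnonzero(state.tfh_busy >= 0)
    for t in engaged:
        b = state.tfh_busy[t]
        if not bc.alive[b] or bc.state[b] != TFH:
            state.tfh_busy[t] = -1
            continue
        bc.polar_t[b] += cfg.dt_h
        bc.contact_t[b] -= cfg.dt_h
        if bc.contact_t[b] <= 0:
            state.tfh_busy[t] = -1
            bc.contact_tfh[b] = -1

    # new contacts: each free Tfh picks its max-antigen free neighbor
    free_t = np.flatnonzero(state.tfh_busy < 0)
    if len(free_t):
        val = np.full(bc.capacity, -1, dtype=np.int64)
        avail = in_window[bc.contact_tfh[in_window] < 0]
        val[avail] = bc.a[avail]
        tflat = (state.tfh_pos[free_t, 0] * D + state.tfh_pos[free_t, 1]) * D \
            + state.tfh_pos[free_t, 2]
        nb = occ_flat[tflat[:, None] + state.off6[None, :]]       # (n_free, 6)
        nb_ok = (nb >= 0) & (nb < 1_000_000)
        nb_val = np.where(nb_ok, val[np.clip(nb, 0, bc.capacity - 1)], -1)
        best = np.argmax(nb_val, axis=1)
        has = nb_val[np.arange(len(best)), best] >= 0
        for row in np.flatnonzero(has):
            t = free_t[row]
            b = nb[row, best[row]]
            if bc.contact_tfh[b] >= 0:      # claimed by an earlier Tfh this step
                continue
            state.tfh_busy[t] = b
            bc.contact_tfh[b] = t
            bc.contact_t[b] = cfg.contact_duration_h

    # window bookkeeping and fate resolution
    bc.window_t[in_window] += cfg.dt_h
    for b in in_window:
        if bc.polar_t[b] >= cfg.polarization_required_h:
            # selected: recycle to DZ with pMHC-dependent divisions
            t = bc.contact_tfh[b]
            if t >= 0:
                state.tfh_busy[t] = -1
                bc.contact_tfh[b] = -1
            bc.state[b] = CB
            bc.div_left[b] = divisions_from_antigen(
                int(bc.a[b]), cfg.div_nmin, cfg.div_nmax, cfg.div_k, cfg.div_h)
            bc.cycle_t[b] = _draw_cycle(state, 1)[0]
        elif bc.window_t[b] >= cfg.tfh_window_h:
            t = bc.contact_tfh[b]
            if t >= 0:
                state.tfh_busy[t] = -1
                bc.contact_tfh[b] = -1
            state.antigen_removed_dead += int(bc.a[b])
            state.occ[tuple(bc.pos[b])] = -1
            bc.kill(b)   # window expired without enough Tfh help


def _outputs_and_antibody(state: GCState) -> None:
    cfg = state.config
    lam = math.log(2.0) / cfg.output_asc_halflife_h
    dd = state.output_pool * (1.0 - math.exp(-lam * cfg.dt_h))
    state.output_pool -= dd
    state.asc += dd
    state.antibody_mol += state.asc * cfg.ab_rate_mol_per_h * cfg.dt_h


def step(state: GCState) -> GCState:
    """Advance the GC by one time step dt (fixed event order, in place)."""
    _influx(state)
    _move_agents(state)
    _divide_cells(state)
    do_capture = (state.step_index + 1) % state.config.capture_every_steps == 0
    _capture_and_search(state, do_capture)
    _tfh_selection(state)
    _outputs_and_antibody(state)
    state.step_index += 1
    state.time_h = state.step_index * state.config.dt_h
    return state


@dataclass
class SimulationResult:
    """A finished GC run: metric time series, egressed output cells, and the
    final state."""

    timeseries: pd.DataFrame
    outputs: pd.DataFrame
    state: GCState
    config: GCConfig
    seed: int

    def summary(self) -> dict:
        ts = self.timeseries
        return {
            "seed": self.seed,
            "final_time_h": float(ts["time_h"].iloc[-1]) if len(ts) else 0.0,
            "peak_gc_size": int(ts["n_bcells"].max()) if len(ts) else 0,
            "final_gc_size": int(ts["n_bcells"].iloc[-1]) if len(ts) else 0,
            "cumulative_outputs": int(self.state.n_outputs),
            "antibody_mol": float(self.state.antibody_mol),
            "ledger": self.state.ledger_balance(),
        }


def run(config: GCConfig, antigen_set: AntigenSet, founder_pool: FounderPool,
        docker: Optional[Docker] = None, seed: Optional[int] = None,
        audit_ledger: bool = False) -> SimulationResult:
    """Run one GC from t=0 to sim_days, recording metrics on the snapshot
    cadence. Deterministic given (config, inputs, seed)."""
    from .metrics import record_snapshot   # local import to avoid cycle

    seed = config.seed if seed is None else seed
    state = initialize(config, antigen_set, founder_pool, docker=docker, seed=seed)
    total_steps = int(round(config.sim_days * 24.0 / config.dt_h))
    snap_every = max(1, int(round(config.snapshot_interval_h / config.dt_h)))
    rows = [record_snapshot(state)]
    for _ in range(total_steps):
        step(state)
        if audit_ledger:
            bal = state.ledger_balance()
            if bal["total"] != config.antigen_total:
                raise AssertionError(
                    f"antigen ledger violated at t={state.time_h:.4f} h: {bal}")
        if state.step_index % snap_every == 0:
            rows.append(record_snapshot(state))
    ts = pd.DataFrame(rows)
    out = pd.DataFrame(state.outputs,
                       columns=["time_h", "seq_id", "mutations",
                                "founder_domain", "antigen_units"])
    if len(out):
        e = state.registry.energies[out["seq_id"].to_numpy()]
        affs = energy_to_affinity(e, state.docker.affinity_params)
        for k, ag in enumerate(antigen_set.domains):
            out[f"affinity_{ag.identity}"] = affs[:, k]
        out["sequence"] = [state.registry.seqs[i] for i in out["seq_id"]]
    return SimulationResult(timeseries=ts, outputs=out, state=state,
                            config=config, seed=seed)


def run_replicates(config: GCConfig, antigen_set: AntigenSet,
                   founder_pool: FounderPool, n: int = 10,
                   base_seed: Optional[int] = None,
                   docker: Optional[Docker] = None) -> tuple[pd.DataFrame, list[SimulationResult]]:
    """n independent seeded runs on a shared time grid; returns per-time
    mean and SD of every metric (long format: metric columns suffixed
    _mean/_sd) plus the individual results."""
    base_seed = config.seed if base_seed is None else base_seed
    results = []
    for i in range(n):
        results.append(run(config, antigen_set, founder_pool, docker=docker,
                           seed=base_seed + 1000 * i))
    stacked = pd.concat([r.timeseries.assign(replicate=i)
                         for i, r in enumerate(results)])
    grouped = stacked.drop(columns="replicate").groupby("time_h")
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=0).add_suffix("_sd")
    return pd.concat([mean, sd], axis=1).reset_index(), results
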