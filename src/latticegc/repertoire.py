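"""Naive BCR repertoires, founder pools, and the somatic hypermutation operator.

BCRs are fixed-length peptides (9 residues by default, a CDRH3 proxy). The
founder pool for a GC with N antigens holds 1000/N sequences per antigen,
rejection-sampled uniformly and kept only if their affinity to the assigned
antigen is at least 1e-4; cross-reactivity to the other antigens is left
untouched. Somatic hypermutation replaces each residue independently with
probability p = 0.055 by one of the 19 other amino acids, so a replacement
is a guaranteed change and the expected number of replacements per division
of a 9-mer is 9 x 0.055 ~ 0.5, matching the headline mutation load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .antigens import AntigenSet
from .docking import Docker, energy_to_affinity
from .lattice import AMINO_ACIDS

__all__ = ["FounderPool", "random_bcr_panel", "generate_founder_pool",
           "mutate", "write_pool_fasta", "read_pool_fasta"]

log = logging.getLogger(__name__)


def random_bcr_panel(n: int, L: int = 9, seed=None,
                     rng: Optional[np.random.Generator] = None) -> list[str]:
    """n i.i.d. uniform random BCR sequences of length L."""
    if n < 1:
        raise ValueError("panel size must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = rng.integers(20, size=(n, L))
    return ["".join(AMINO_ACIDS[i] for i in row) for row in idx]


def mutate(seq: str, p: float, rng: np.random.Generator) -> tuple[str, int]:
    """Somatic hypermutation: replace each residue independently with
    probability p by a uniform draw among the 19 *other* residues.

    Returns (new sequence, number of replaced positions). Multiple
    simultaneous replacements are allowed; n_changes ~ Binomial(L, p).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mutation probability must be in [0, 1], got {p}")
    hits = rng.random(len(seq)) < p
    if not hits.any():
        return seq, 0
    out = list(seq)
    for i in np.flatnonzero(hits):
        old = out[i]
        choices = AMINO_ACIDS.replace(old, "")
        out[i] = choices[rng.integers(19)]
    return "".join(out), int(hits.sum())


@dataclass(frozen=True)
class FounderPool:
    """Per-antigen founder BCR sequences with provenance."""

    sequences: dict[str, tuple[str, ...]]   # antigen identity -> sequences
    min_affinity: float
    seed: Optional[int] = None

    @property
    def all_sequences(self) -> list[tuple[str, str]]:
        """Flat [(antigen identity, sequence)] list in stable order."""
        return [(ag, s) for ag, seqs in self.sequences.items() for s in seqs]

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.sequences.values())


def generate_founder_pool(antigen_set: AntigenSet, docker: Docker,
                          pool_total: int = 1000, min_affinity: float = 1e-4,
                          seed=None, max_attempts: int = 2_000_000,
                          injected: Optional[dict[str, Sequence[str]]] = None,
                          enforce_floor_on_injected: bool = True,
                          batch: int = 512) -> FounderPool:
    """Rejection-sample the naive founder pool: pool_total/N uniform random
    sequences per antigen, each required to bind its assigned antigen with
    affinity >= min_affinity (1e-4 by default).

    ``injected`` sequences (memory-like founders) bypass sampling but still
    face the affinity floor unless ``enforce_floor_on_injected`` is False.
    Fails with the best affinity observed if an antigen's quota cannot be
    met within ``max_attempts`` samples (an unbindable antigen or a
    threshold mismatch).
    """
    n_domains = antigen_set.n_domains
    quota, rem = divmod(pool_total, n_domains)
    if rem:
        log.warning("pool_total=%d not divisible by %d antigens; "
                    "using %d per antigen (%d dropped)",
                    pool_total, n_domains, quota, rem)
    rng = np.random.default_rng(seed)
    params = docker.affinity_params
    pools: dict[str, tuple[str, ...]] = {}
    for antigen in antigen_set.domains:
        accepted: list[str] = []
        if injected and antigen.identity in injected:
            for s in injected[antigen.identity]:
                if enforce_floor_on_injected:
                    aff = docker.affinity(s, antigen)
                    if aff < min_affinity:
                        raise ValueError(
                            f"injected founder {s} has affinity {aff:.3g} < "
                            f"{min_affinity} to antigen {antigen.identity}")
                accepted.append(s)
        attempts = 0
        best_aff = 0.0
        while len(accepted) < quota:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"founder sampling for antigen {antigen.identity!r} "
                    f"exhausted {max_attempts} attempts with only "
                    f"{len(accepted)}/{quota} accepted; best affinity seen "
                    f"{best_aff:.3g} vs floor {min_affinity:.3g}")
            n = min(batch, max_attempts - attempts)
            cands = random_bcr_panel(n, L=docker.L, rng=rng)
            attempts += n
            if min_affinity <= 0:
                accepted.extend(cands[:quota - len(accepted)])
                continue
            energies = docker.batch_energies(cands, antigen)
            affs = energy_to_affinity(energies, params)
            best_aff = max(best_aff, float(np.max(affs)))
            for s, a in zip(cands, affs):
                if a >= min_affinity:
                    accepted.append(s)
                    if len(accepted) == quota:
                        break
        pools[antigen.identity] = tuple(accepted[:quota] if quota else accepted)
    return FounderPool(pools, min_affinity=min_affinity,
                       seed=seed if isinstance(seed, int) else None)


def write_pool_fasta(pool: FounderPool, path) -> None:
    records = []
    for ag, seqs in pool.sequences.items():
        for i, s in enumerate(seqs):
            records.append(SeqRecord(Seq(s), id=f"{ag}|founder{i}",
                                     description=f"min_affinity={pool.min_affinity}"))
    SeqIO.write(records, str(path), "fasta")


def read_pool_fasta(path, min_affinity: float = 1e-4) -> FounderPool:
    pools: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        ag = rec.id.split("|", 1)[0]
        pools.setdefault(ag, []).append(str(rec.seq))
    if not pools:
        raise ValueError(f"no founder records in {path}")
    return FounderPool({k: tuple(v) for k, v in pools.items()},
                       min_affinity=min_affinity)
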