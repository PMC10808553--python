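"""Independent naive docking enumerator used as the test oracle.

Enumerates every self-avoiding walk of the BCR around the antigen by plain
recursive search over a bounding box (no pruning, no profile deduplication,
no compiled code) and scores sequences directly from the geometry. Kept
deliberately separate from the package's engine.
"""

from __future__ import annotations

import numpy as np

STEPS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def enumerate_naive(antigen, L, min_contacts=1, margin=None):
    """All valid poses as (inter, intra) contact lists.

    inter: list of (bcr_index, antigen_residue_letter); intra: list of
    (i, j) with j <= i-2. Returned in a deterministic order (start nodes
    lexicographic, directions as in STEPS).
    """
    chain = antigen.structure if hasattr(antigen, "structure") else antigen
    ag_nodes = {p: r for p, r in zip(chain.positions, chain.residues)}
    coords = np.array(chain.positions)
    margin = L + 1 if margin is None else margin
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    poses = []

    def contacts_of(walk):
        inter, intra = [], []
        for i, p in enumerate(walk):
            for d in STEPS:
                q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if q in ag_nodes:
                    inter.append((i, ag_nodes[q]))
            for j in range(i - 1):
                if sum(abs(a - b) for a, b in zip(p, walk[j])) == 1:
                    intra.append((i, j))
        return inter, intra

    def grow(walk):
        if len(walk) == L:
            inter, intra = contacts_of(walk)
            if len(inter) >= min_contacts:
                poses.append((inter, intra))
            return
        p = walk[-1]
        for d in STEPS:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if q in ag_nodes or q in walk:
                continue
            if not all(lo[k] <= q[k] <= hi[k] for k in range(3)):
                continue
            grow(walk + [q])

    for x in range(lo[0], hi[0] + 1):
        for y in range(lo[1], hi[1] + 1):
            for z in range(lo[2], hi[2] + 1):
                if (x, y, z) not in ag_nodes:
                    grow([(x, y, z)])
    return poses


class NaiveDocker:
    """Scores sequences against naively enumerated poses with numpy sums
    (no profile sharing with the engine under test)."""

    def __init__(self, antigen, L, potential, min_contacts=1, stabilization=1.0):
        self.poses = enumerate_naive(antigen, L, min_contacts)
        self.s = stabilization
        self.pot = potential
        # flatten to arrays per pose for fast per-sequence scoring
        self._inter = [(np.array([i for i, _ in inter], dtype=int),
                        np.array([self.pot._index[r] for _, r in inter], dtype=int))
                       for inter, _ in self.poses]
        self._intra = [(np.array([i for i, _ in intra], dtype=int),
                        np.array([j for _, j in intra], dtype=int))
                       for _, intra in self.poses]

    @property
    def n_poses(self):
        return len(self.poses)

    def min_energy(self, seq):
        sidx = np.array([self.pot._index[c] for c in seq], dtype=int)
        U = self.pot.matrix
        best = np.inf
        for (ii, rr), (ai, aj) in zip(self._inter, self._intra):
            e = U[sidx[ii], rr].sum() + self.s * U[sidx[ai], sidx[aj]].sum()
            if e < best:
                best = e
        return best
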