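"""Cubic-lattice geometry: points, chains, rotations and the structure file format.

Two independent lattices share this geometry: the cellular lattice of the
germinal center (one node = 5 micrometers) and the molecular lattice on which
antigens and B-cell receptors are folded (one node = 5.25 angstroms, one amino
acid per node). Adjacency is strictly the 6-neighborhood (von Neumann);
diagonal nodes never touch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np

#: Canonical amino-acid ordering (Miyazawa-Jernigan order, matches the
#: packaged contact-potential resource).
AMINO_ACIDS = "CMFILVWYAGTSNQDEHRKP"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: The six unit steps of the cubic lattice, in the fixed enumeration order
#: used everywhere (+x, -x, +y, -y, +z, -z).
UNIT_STEPS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
)

Point = tuple[int, int, int]


def neighbors(p: Sequence[int]) -> set[Point]:
    """The six von Neumann neighbors of a lattice point."""
    x, y, z = p
    return {(x + dx, y + dy, z + dz) for dx, dy, dz in UNIT_STEPS}


def are_adjacent(p: Sequence[int], q: Sequence[int]) -> bool:
    return sum(abs(a - b) for a, b in zip(p, q)) == 1


@dataclass(frozen=True)
class LatticeChain:
    """A self-avoiding chain of residues on the cubic lattice.

    ``positions`` and ``residues`` are parallel: residue ``i`` sits at
    ``positions[i]``. Consecutive residues are covalently bound and must be
    lattice neighbors.
    """

    positions: tuple[Point, ...]
    residues: str

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.residues):
            raise ValueError(
                f"chain has {len(self.positions)} positions but "
                f"{len(self.residues)} residues"
            )
        if len(self.positions) < 1:
            raise ValueError("chain must have at least one residue")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.positions, dtype=np.int64)

    def with_residues(self, residues: str) -> "LatticeChain":
        return LatticeChain(self.positions, residues)

    def translated(self, offset: Sequence[int]) -> "LatticeChain":
        ox, oy, oz = offset
        return LatticeChain(
            tuple((x + ox, y + oy, z + oz) for x, y, z in self.positions),
            self.residues,
        )

    def rotated(self, rot: np.ndarray) -> "LatticeChain":
        new = (self.coords @ np.asarray(rot, dtype=np.int64).T)
        return LatticeChain(tuple(map(tuple, new.tolist())), self.residues)


def validate_chain(chain: LatticeChain) -> bool:
    """True iff the chain is self-avoiding with consecutive residues adjacent.

    Returns False rather than raising so callers can use it as a predicate.
    """
    pos = chain.positions
    if len(set(pos)) != len(pos):
        return False
    return all(are_adjacent(pos[i], pos[i + 1]) for i in range(len(pos) - 1))


def lattice_rotations() -> list[np.ndarray]:
    """The 24 proper rotations of the cubic lattice (signed permutation
    matrices with determinant +1)."""
    rots = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=np.int64)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if round(np.linalg.det(m)) == 1:
                rots.append(m)
    return rots


# ---------------------------------------------------------------------------
# Plain-text lattice structure format: one line per residue,
# "index residue x y z", '#' comments, shared by import and export.
# ---------------------------------------------------------------------------

def write_structure(chain: LatticeChain, handle: TextIO, comment: str = "") -> None:
    if comment:
        for line in comment.splitlines():
            handle.write(f"# {line}\n")
    handle.write("# index residue x y z\n")
    for i, (res, (x, y, z)) in enumerate(zip(chain.residues, chain.positions)):
        handle.write(f"{i} {res} {x} {y} {z}\n")


def read_structure(handle: TextIO) -> LatticeChain:
    positions: list[Point] = []
    residues: list[str] = []
    seen: set[Point] = set()
    for lineno, raw in enumerate(handle, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"line {lineno}: expected 'index residue x y z', got {raw!r}")
        _, res, xs, ys, zs = parts
        if res not in AA_INDEX:
            raise ValueError(f"line {lineno}: unknown residue letter {res!r}")
        try:
            p = (int(xs), int(ys), int(zs))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer coordinate in {raw!r}") from exc
        if p in seen:
            raise ValueError(f"line {lineno}: duplicate lattice node {p}")
        if positions and not are_adjacent(positions[-1], p):
            raise ValueError(
                f"line {lineno}: residue at {p} is not adjacent to previous "
                f"residue at {positions[-1]}"
            )
        seen.add(p)
        positions.append(p)
        residues.append(res)
    if not positions:
        raise ValueError("structure file contains no residues")
    return LatticeChain(tuple(positions), "".join(residues))


def residues_to_indices(residues: str) -> np.ndarray:
    """Encode a residue string as uint8 indices into AMINO_ACIDS."""
    try:
        return np.array([AA_INDEX[r] for r in residues], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from exc


def indices_to_residues(idx: Iterable[int]) -> str:
    return "".join(AMINO_ACIDS[i] for i in idx)
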