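"""The 20x20 amino-acid contact-energy potential.

Binding energies of lattice proteins are sums of pairwise contact energies
over non-covalent nearest-neighbor residue pairs. The packaged default is a
transcription of the empirical Miyazawa-Jernigan (1996) contact energies
(Table 5, e_ij, kT units); any table in the same text format can be swapped
in, including an all-zero table used by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TextIO, Union

import numpy as np

from .lattice import AMINO_ACIDS

DEFAULT_POTENTIAL = "mj1996"

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class PotentialMatrix:
    """Symmetric 20x20 contact-energy table, indexed by amino-acid letter."""

    matrix: np.ndarray
    order: str = AMINO_ACIDS
    name: str = "custom"
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (20, 20):
            raise ValueError(f"potential must be 20x20, got {m.shape}")
        if not np.isfinite(m).all():
            bad = np.argwhere(~np.isfinite(m))[0]
            raise ValueError(f"non-finite potential entry at {tuple(bad)}")
        asym = np.abs(m - m.T)
        if asym.max() > _SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"asymmetric potential: U({self.order[i]},{self.order[j]})="
                f"{m[i, j]} but U({self.order[j]},{self.order[i]})={m[j, i]}"
            )
        if sorted(self.order) != sorted(AMINO_ACIDS) or len(self.order) != 20:
            raise ValueError("residue order must be a permutation of the 20 standard letters")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "_index", {aa: i for i, aa in enumerate(self.order)})

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return contact_energy(a, b, self)

    def reindexed(self, order: str = AMINO_ACIDS) -> np.ndarray:
        """The matrix permuted to a given residue ordering (default: the
        package-canonical order used by the docking engine)."""
        perm = [self._index[aa] for aa in order]
        return self.matrix[np.ix_(perm, perm)]

    @classmethod
    def zeros(cls) -> "PotentialMatrix":
        return cls(np.zeros((20, 20)), name="zero")


def contact_energy(a: str, b: str, potential: PotentialMatrix) -> float:
    """Contact energy U(a, b) in kT; commutative in its arguments."""
    try:
        return float(potential.matrix[potential._index[a], potential._index[b]])
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from exc


def _parse_rows(handle: TextIO) -> tuple[str, list[list[float]]]:
    order = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if order is None:
            order = "".join(parts)
            if len(order) != 20:
                raise ValueError(
                    f"line {lineno}: header must list 20 residue letters, got {order!r}"
                )
            continue
        try:
            rows.append([float(tok) for tok in parts])
        except ValueError:
            raise ValueError(f"line {lineno}: malformed numeric entry in {raw!r}") from None
    if order is None:
        raise ValueError("potential file has no header line")
    return order, rows


def load_potential(source: Union[str, Path, TextIO, None] = None) -> PotentialMatrix:
    """Load a contact potential from a file path, open handle, or by the name
    of a packaged resource (default: the Miyazawa-Jernigan 1996 table).

    Accepts a full 20x20 matrix (checked for symmetry) or a lower triangle
    (row i holding i+1 entries, mirrored on load).
    """
    if source is None:
        source = DEFAULT_POTENTIAL
    name = "custom"
    if hasattr(source, "read"):
        order, rows = _parse_rows(source)
    else:
        path = Path(str(source))
        if not path.exists():
            res = resources.files("latticegc").joinpath(f"data/{source}.txt")
            if not res.is_file():
                raise FileNotFoundError(f"no potential file or packaged resource named {source!r}")
            name = str(source)
            with res.open("r") as fh:
                order, rows = _parse_rows(fh)
        else:
            name = path.stem
            with open(path) as fh:
                order, rows = _parse_rows(fh)
    if len(rows) != 20:
        raise ValueError(f"expected 20 matrix rows, got {len(rows)}")
    lengths = [len(r) for r in rows]
    m = np.zeros((20, 20))
    if lengths == [20] * 20:
        m = np.asarray(rows)
    elif lengths == list(range(1, 21)):
        for i, row in enumerate(rows):
            for j, v in enumerate(row):
                m[i, j] = m[j, i] = v
    else:
        raise ValueError(
            f"rows must form a full 20x20 matrix or a lower triangle; row lengths {lengths}"
        )
    return PotentialMatrix(m, order=order, name=name)
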