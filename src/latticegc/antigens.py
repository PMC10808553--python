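"""Antigen generation, immunogenicity classification, and antigen sets.

Antigen structures are self-avoiding chains on the molecular lattice. In the
reference workflow the structures derive from discretized PDB proteins; here
structures are generated synthetically (compactness-biased self-avoiding
walks) or imported from the plain-text lattice-structure format, and amino
acids are assigned uniformly at random to every node. Surface exposure is
emergent: buried residues simply cannot be contacted by a docked BCR.

Immunogenicity of an antigen is operationalized as its mean optimal binding
energy against a panel of random naive BCR sequences (200 by default).
Classes A..H partition the mean-energy axis from below -75 kT (class A,
highly immunogenic) in 2.5 kT steps up to above -60 kT (class H, weakly
immunogenic); a boundary value belongs to the less immunogenic class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .docking import Docker
from .lattice import (AMINO_ACIDS, LatticeChain, UNIT_STEPS, neighbors,
                      read_structure, validate_chain, write_structure)

__all__ = [
    "Antigen", "AntigenSet", "IMMUNOGENICITY_CLASSES",
    "generate_structure", "randomize_residues", "average_panel_energy",
    "classify_immunogenicity", "build_antigen_set",
    "import_structure", "export_structure",
]


@dataclass(frozen=True)
class Antigen:
    """A lattice antigen: structure plus identity and (optional) class."""

    structure: LatticeChain
    identity: str
    class_label: str = "unassigned"

    def __post_init__(self) -> None:
        if not validate_chain(self.structure):
            raise ValueError(f"antigen {self.identity!r} has an invalid lattice chain")

    def __len__(self) -> int:
        return len(self.structure)

    @property
    def residues(self) -> str:
        return self.structure.residues


@dataclass(frozen=True)
class AntigenSet:
    """Antigen domains displayed together in one GC, dosed equally."""

    domains: tuple[Antigen, ...]
    total_dose: int = 3000

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("antigen set must contain at least one domain")
        ids = [a.identity for a in self.domains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate antigen identities in set: {ids}")
        if self.total_dose <= 0:
            raise ValueError("total_dose must be positive")

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def per_domain_dose(self) -> float:
        return self.total_dose / len(self.domains)

    @property
    def identities(self) -> list[str]:
        return [a.identity for a in self.domains]


def build_antigen_set(antigens: Sequence[Antigen], total_dose: int = 3000) -> AntigenSet:
    """Assemble antigens into a multi-domain set with the total dose split
    equally across domains (3000 units total by default)."""
    return AntigenSet(tuple(antigens), total_dose=total_dose)


# ---------------------------------------------------------------------------
# Structure generation
# ---------------------------------------------------------------------------

def generate_structure(n_residues: int, seed, compactness: float = 1.0,
                       max_restarts: int = 1000) -> LatticeChain:
    """Grow a self-avoiding chain of ``n_residues`` nodes on the lattice.

    Each growth step chooses among the free neighbors of the chain head with
    weight exp(compactness * k), where k is the number of already-occupied
    (non-head) chain nodes adjacent to the candidate. compactness = 0 gives
    the uniform self-avoiding walk; larger values fold the chain onto itself,
    emulating globular antigens. Dead ends trigger a restart with a fresh
    sub-seed; generation fails after ``max_restarts`` restarts.
    """
    if n_residues < 4:
        raise ValueError(f"antigen needs >= 4 residues, got {n_residues}")
    root = np.random.default_rng(seed)
    for attempt in range(max_restarts):
        rng = np.random.default_rng(root.integers(2**31))
        positions = [(0, 0, 0)]
        occupied = {(0, 0, 0)}
        while len(positions) < n_residues:
            head = positions[-1]
            cands = [q for q in sorted(neighbors(head)) if q not in occupied]
            if not cands:
                break
            contacts = np.array(
                [sum((r in occupied) and r != head for r in neighbors(q)) for q in cands],
                dtype=np.float64)
            w = np.exp(compactness * contacts)
            q = cands[rng.choice(len(cands), p=w / w.sum())]
            positions.append(q)
            occupied.add(q)
        if len(positions) == n_residues:
            chain = LatticeChain(tuple(positions), "A" * n_residues)
            assert validate_chain(chain)
            return chain
    raise RuntimeError(
        f"failed to grow a {n_residues}-residue self-avoiding chain after "
        f"{max_restarts} restarts")


def randomize_residues(structure: LatticeChain, seed, identity: str = "AG",
                       alphabet: str = AMINO_ACIDS) -> Antigen:
    """Assign an independent uniform random residue to every node of the
    structure (geometry untouched)."""
    rng = np.random.default_rng(seed)
    letters = "".join(alphabet[i] for i in rng.integers(len(alphabet), size=len(structure)))
    return Antigen(structure.with_residues(letters), identity=identity)


# ---------------------------------------------------------------------------
# Immunogenicity
# ---------------------------------------------------------------------------

#: Class label -> half-open mean-energy interval [lo, hi) in kT. A boundary
#: value falls in the class to its right (less immunogenic).
IMMUNOGENICITY_CLASSES: dict[str, tuple[float, float]] = {
    "A": (-np.inf, -75.0),
    "B": (-75.0, -72.5),
    "C": (-72.5, -70.0),
    "D": (-70.0, -67.5),
    "E": (-67.5, -65.0),
    "F": (-65.0, -62.5),
    "G": (-62.5, -60.0),
    "H": (-60.0, np.inf),
}


def classify_immunogenicity(mean_energy: float) -> str:
    """Map a panel-mean binding energy (kT) to its immunogenicity class."""
    if not np.isfinite(mean_energy):
        raise ValueError(f"mean energy must be finite, got {mean_energy}")
    for label, (lo, hi) in IMMUNOGENICITY_CLASSES.items():
        if lo <= mean_energy < hi:
            return label
    raise AssertionError("unreachable: class intervals partition the line")


def average_panel_energy(antigen: Antigen, panel: Sequence[str],
                         docker: Docker) -> float:
    """Arithmetic mean of the optimal binding energies of a panel of BCR
    sequences against one antigen (the immunogenicity readout; 200 random
    9-mers in the reference protocol)."""
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    return float(docker.batch_energies(list(panel), antigen).mean())


def classify_antigen(antigen: Antigen, panel: Sequence[str],
                     docker: Docker) -> Antigen:
    """Return the antigen annotated with its immunogenicity class."""
    label = classify_immunogenicity(average_panel_energy(antigen, panel, docker))
    return Antigen(antigen.structure, antigen.identity, class_label=label)


# ---------------------------------------------------------------------------
# File I/O (plain-text lattice structure format, shared with structure core)
# ---------------------------------------------------------------------------

def export_structure(antigen: Antigen, path) -> None:
    with open(path, "w") as fh:
        write_structure(antigen.structure, fh,
                        comment=f"antigen {antigen.identity} class {antigen.class_label}")


def import_structure(path, identity: Optional[str] = None) -> Antigen:
    with open(path) as fh:
        chain = read_structure(fh)
    return Antigen(chain, identity=identity or str(path))
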