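"""Seeded toy fixtures: small antigens, screened high/low-immunogenicity
pairs, panels, founder pools and a reduced-scale GC configuration.

Full-protocol GC runs (9-mer BCRs on 100+-residue antigens, 1e-4 h steps,
21 days) are multi-CPU-hour computations. The fixtures here define a
reduced molecular and cellular scale on which every mechanism still
operates: 5-residue BCRs docked on ~10-residue compact antigens, a 80-um GC
with proportionally fewer stromal agents, and coarser 0.01 h steps. Because
short BCRs make far fewer lattice contacts, the energy scale shrinks, so
the toy affinity map uses Emax matched to the toy energy range (the map is
the same exponential; only its anchor moves). All fixtures are pure
functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .antigens import (Antigen, AntigenSet, average_panel_energy,
                       build_antigen_set, generate_structure,
                       randomize_residues)
from .config import GCConfig
from .docking import AffinityParams, Docker
from .potential import load_potential
from .repertoire import FounderPool, generate_founder_pool, random_bcr_panel

__all__ = ["FixtureBundle", "make_fixtures", "toy_config", "toy_docker",
           "tiny_antigen", "small_antigen", "screened_pair"]

#: Toy molecular scale (see module docstring).
TOY_L = 5
TOY_MIN_CONTACTS = 2
TOY_EMAX = -44.0
TOY_FOUNDER_MIN_AFF = 1e-2
TOY_ANTIGEN_RES = 10


def toy_config(**overrides) -> GCConfig:
    """Reduced-scale GC configuration used by the test suite and examples.

    Scaled knobs (see the methods note for the reasoning): the GC radius,
    stromal agent counts and run length shrink roughly with the tenth-scale
    cell population; the affinity anchor Emax moves to the 5-mer energy
    range; the founder affinity floor rises to 1e-2 so that floor founders
    keep the same ~5-10% chance of capturing during one light-zone sojourn
    as in the full protocol; capture_rate 0.15 compensates the upward-
    compressed toy affinity distribution so antigen stays scarce instead of
    exhausting; and the division-number Hill constant scales from 9 to 1.5
    captured units to match the smaller per-sojourn capture counts."""
    base = dict(
        gc_radius_um=80.0, n_tfh=40, n_fdc=30, arm_length_um=20.0,
        n_stromal=40, dt_h=0.01, capture_interval_h=0.01, sim_days=8.0,
        founder_divisions=4, div_nmax=5, div_k=1.5, capture_rate=0.15,
        founder_pool_total=200, founder_min_affinity=TOY_FOUNDER_MIN_AFF,
        bcr_length=TOY_L, min_contacts=TOY_MIN_CONTACTS,
        emax=TOY_EMAX, max_poses=20_000_000,
    )
    base.update(overrides)
    return GCConfig(**base)


def toy_docker(config: GCConfig = None) -> Docker:
    cfg = config or toy_config()
    return Docker(load_potential(), L=cfg.bcr_length,
                  min_contacts=cfg.min_contacts,
                  stabilization=cfg.stabilization,
                  affinity_params=cfg.affinity_params,
                  max_poses=cfg.max_poses)


def tiny_antigen(seed: int = 0, n_res: int = 6, identity: str = "tiny") -> Antigen:
    """A <=8-residue compact antigen for oracle-equivalence tests."""
    structure = generate_structure(n_res, seed=seed, compactness=1.5)
    return randomize_residues(structure, seed=seed + 1, identity=identity)


def small_antigen(seed: int = 0, n_res: int = 20, identity: str = "small") -> Antigen:
    structure = generate_structure(n_res, seed=seed, compactness=1.5)
    return randomize_residues(structure, seed=seed + 1, identity=identity)


def screen_antigens(seed: int = 0, docker: Docker = None,
                    n_res: int = TOY_ANTIGEN_RES, panel_size: int = 50,
                    min_gap_kt: float = 5.0, max_rounds: int = 40,
                    batch: int = 10) -> tuple[Antigen, Antigen, Antigen]:
    """(high, mid, low)-immunogenicity antigens on one shared structure.

    Residue assignments are screened against a random BCR panel until the
    running best (lowest mean energy) and worst (highest) candidates differ
    by at least ``min_gap_kt``; the loop guarantees the gap or raises. The
    mid antigen is the screened candidate closest to the hi/lo midpoint."""
    docker = docker or toy_docker()
    structure = generate_structure(n_res, seed=seed, compactness=1.5)
    panel = random_bcr_panel(panel_size, L=docker.L, seed=seed + 7)
    cands: list[tuple[Antigen, float]] = []
    for round_idx in range(max_rounds):
        for j in range(batch):
            ag = randomize_residues(structure, seed=seed * 100_000 + round_idx * batch + j,
                                    identity="cand")
            cands.append((ag, average_panel_energy(ag, panel, docker)))
        best = min(cands, key=lambda c: c[1])
        worst = max(cands, key=lambda c: c[1])
        if worst[1] - best[1] >= min_gap_kt:
            midpoint = 0.5 * (best[1] + worst[1])
            mid = min(cands, key=lambda c: abs(c[1] - midpoint))
            return (Antigen(best[0].structure, "HI", class_label="hi"),
                    Antigen(mid[0].structure, "MID", class_label="mid"),
                    Antigen(worst[0].structure, "LO", class_label="lo"))
    raise RuntimeError(
        f"screening failed to find a pair with >= {min_gap_kt} kT panel-mean "
        f"gap after {max_rounds * batch} candidates "
        f"(best gap {worst[1] - best[1]:.2f} kT)")


def screened_pair(seed: int = 0, docker: Docker = None, **kwargs) -> tuple[Antigen, Antigen]:
    hi, _, lo = screen_antigens(seed, docker, **kwargs)
    return hi, lo


def fullscale_antigen_pair(seed: int = 0) -> tuple[Antigen, Antigen, Docker]:
    """Two compact hydrophobic-rich 12-residue antigens plus a 9-mer docking
    engine at the full-protocol affinity scale (Emax = -100).

    Docking uses min_contacts = 9 (one antigen contact per BCR residue on
    average), which keeps exhaustive enumeration around a 12-mer tractable
    while preserving the full energy range; the hydrophobic-biased surface
    keeps the naive-repertoire acceptance rate at the 1e-4 affinity floor
    workable for rejection sampling."""
    hydrophobic = "FILMVWYC"
    docker = Docker(load_potential(), L=9, min_contacts=9,
                    affinity_params=AffinityParams())
    ags = []
    sub_seed = seed * 1000 + 5
    for i, name in enumerate(("AG1", "AG2")):
        # not every 12-mer walk is compact enough to admit 9-contact poses:
        # advance the structure seed until the pose set is non-trivial
        for _ in range(50):
            structure = generate_structure(12, seed=sub_seed, compactness=2.5)
            sub_seed += 1
            ag = randomize_residues(structure, seed=seed + 100 + i,
                                    identity=name, alphabet=hydrophobic)
            if docker.pose_set(ag).n_profiles >= 1000:
                ags.append(ag)
                break
        else:
            raise RuntimeError("no sufficiently compact 12-mer structure found")
    return ags[0], ags[1], docker


@dataclass
class FixtureBundle:
    tiny: Antigen
    small: Antigen
    hi: Antigen
    mid: Antigen
    lo: Antigen
    panel: list
    pool: FounderPool
    config: GCConfig
    docker: Docker


def make_fixtures(seed: int = 0) -> FixtureBundle:
    """The standard seeded test bundle: tiny and small antigens, screened
    high/mid/low immunogenicity antigens, a 200-sequence panel, and a
    founder pool for the hi/lo pair at the toy affinity floor."""
    cfg = toy_config()
    docker = toy_docker(cfg)
    hi, mid, lo = screen_antigens(seed, docker)
    pool = generate_founder_pool(
        build_antigen_set([hi, lo], total_dose=cfg.antigen_total), docker,
        pool_total=cfg.founder_pool_total,
        min_affinity=cfg.founder_min_affinity, seed=seed + 13)
    return FixtureBundle(
        tiny=tiny_antigen(seed), small=small_antigen(seed),
        hi=hi, mid=mid, lo=lo,
        panel=random_bcr_panel(200, L=cfg.bcr_length, seed=seed + 3),
        pool=pool, config=cfg, docker=docker)
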