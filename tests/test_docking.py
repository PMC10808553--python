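import math

import numpy as np
import pytest

from latticegc.antigens import Antigen
from latticegc.docking import (AffinityParams, Docker, affinity_to_energy,
                               energy_to_affinity, enumerate_poses,
                               profile_energy)
from latticegc.fixtures import tiny_antigen
from latticegc.lattice import LatticeChain, lattice_rotations
from latticegc.potential import PotentialMatrix, load_potential
from latticegc.repertoire import random_bcr_panel

from oracle import NaiveDocker, enumerate_naive


def l_antigen():
    """A fixed 4-residue L-shaped antigen for cheap exact checks."""
    return Antigen(LatticeChain(((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)),
                                "CWFK"), "L4")


class TestAffinityMap:
    def test_affinity_one_at_emax(self):
        assert energy_to_affinity(-100.0) == pytest.approx(1.0)

    def test_founder_threshold_energy(self):
        # affinity 1e-4 floor sits just below E = -74.2 kT
        assert energy_to_affinity(-74.2) == pytest.approx(
            math.exp((-100 + 74.2) / 2.8))
        assert energy_to_affinity(-74.2) == pytest.approx(9.96e-5, rel=1e-3)

    def test_stronger_than_emax_exceeds_one(self):
        assert energy_to_affinity(-110.0) == pytest.approx(math.exp(10 / 2.8))
        assert energy_to_affinity(-110.0) > 1

    def test_strictly_monotone_decreasing_in_energy(self):
        e = np.linspace(-120, -40, 100)
        a = energy_to_affinity(e)
        assert (np.diff(a) < 0).all()

    def test_literal_mode_is_printed_sign(self):
        lit = AffinityParams(mode="literal")
        assert energy_to_affinity(-90.0, lit) == pytest.approx(math.exp(10 / 2.8))

    def test_inverse_roundtrip(self):
        for aff in (1e-8, 1e-4, 0.5, 1.0, 35.0):
            e = affinity_to_energy(aff)
            assert energy_to_affinity(e) == pytest.approx(aff, rel=1e-12)
        assert affinity_to_energy(1.0) == pytest.approx(-100.0)
        # capture floor 1e-8 maps to roughly -48.4 kT
        assert affinity_to_energy(1e-8) == pytest.approx(-100 + 2.8 * math.log(1e8))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AffinityParams(c=0.0)
        with pytest.raises(ValueError):
            affinity_to_energy(0.0)


class TestEnumeration:
    def test_pose_count_matches_naive_enumerator_single_residue(self):
        ag = Antigen(LatticeChain(((0, 0, 0),), "W"), "1res")
        ps = enumerate_poses(ag, L=2, min_contacts=1)
        naive = enumerate_naive(ag, L=2, min_contacts=1)
        assert ps.n_poses == len(naive)

    def test_pose_count_matches_naive_enumerator_l_antigen(self):
        ps = enumerate_poses(l_antigen(), L=3, min_contacts=1)
        assert ps.n_poses == len(enumerate_naive(l_antigen(), L=3, min_contacts=1))
        assert ps.multiplicity.sum() == ps.n_poses

    def test_impossible_min_contacts_gives_empty_set(self):
        ps = enumerate_poses(l_antigen(), L=3, min_contacts=2 * 3 + 3)
        assert ps.n_profiles == 0 and ps.n_poses == 0

    def test_pose_count_invariant_under_lattice_rotations(self):
        base = enumerate_poses(l_antigen(), L=4, min_contacts=2)
        for rot in lattice_rotations()[:8]:
            rotated = Antigen(l_antigen().structure.rotated(rot).translated((2, -1, 5)),
                              "rot")
            ps = enumerate_poses(rotated, L=4, min_contacts=2)
            assert ps.n_poses == base.n_poses
            assert ps.n_profiles == base.n_profiles

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            enumerate_poses(l_antigen(), L=1)
        with pytest.raises(ValueError):
            enumerate_poses(l_antigen(), L=3, min_contacts=0)

    def test_pose_cap_raises_memory_guard(self):
        with pytest.raises(MemoryError, match="cap"):
            enumerate_poses(tiny_antigen(0), L=5, min_contacts=1, max_poses=100)


class TestScoring:
    def test_energies_match_naive_oracle_exactly(self, potential):
        ag = l_antigen()
        docker = Docker(potential, L=4, min_contacts=1)
        naive = NaiveDocker(ag, L=4, potential=potential, min_contacts=1)
        for seq in random_bcr_panel(40, L=4, seed=7):
            assert docker.binding_energy(seq, ag).energy == pytest.approx(
                naive.min_energy(seq), abs=1e-9)

    def test_energy_invariant_under_rotation_translation(self, potential):
        ag = l_antigen()
        docker = Docker(potential, L=4, min_contacts=1)
        seqs = random_bcr_panel(10, L=4, seed=3)
        base = [docker.binding_energy(s, ag).energy for s in seqs]
        rot = lattice_rotations()[7]
        moved = Antigen(ag.structure.rotated(rot).translated((-4, 2, 9)), "m")
        docker2 = Docker(potential, L=4, min_contacts=1)
        for s, e in zip(seqs, base):
            assert docker2.binding_energy(s, moved).energy == pytest.approx(e, abs=1e-9)

    def test_zero_potential_gives_zero_energy_affinity_anchor(self):
        docker = Docker(PotentialMatrix.zeros(), L=3, min_contacts=1,
                        affinity_params=AffinityParams(emax=-10))
        res = docker.binding_energy("AAA", l_antigen())
        assert res.energy == 0.0
        assert res.affinity == pytest.approx(energy_to_affinity(0.0, AffinityParams(emax=-10)))

    def test_scaled_potential_scales_optimum_and_keeps_pose(self, potential):
        lam = 2.5
        scaled = PotentialMatrix(lam * potential.matrix, order=potential.order)
        d1 = Docker(potential, L=4, min_contacts=1, stabilization=0.0)
        d2 = Docker(scaled, L=4, min_contacts=1, stabilization=0.0)
        for seq in random_bcr_panel(10, L=4, seed=11):
            r1 = d1.binding_energy(seq, l_antigen())
            r2 = d2.binding_energy(seq, l_antigen())
            assert r2.energy == pytest.approx(lam * r1.energy, abs=1e-9)
            assert r2.pose_id == r1.pose_id

    def test_energy_ordering_reverses_affinity_ordering(self, potential):
        docker = Docker(potential, L=4, min_contacts=1)
        seqs = random_bcr_panel(25, L=4, seed=5)
        res = [docker.binding_energy(s, l_antigen()) for s in seqs]
        by_energy = np.argsort([r.energy for r in res])
        by_affinity = np.argsort([-r.affinity for r in res])
        assert list(by_energy) == list(by_affinity)

    def test_profile_energy_matches_geometric_rewalk(self, potential):
        """Score one profile by independently re-walking its decoded pose."""
        ag = l_antigen()
        docker = Docker(potential, L=4, min_contacts=1)
        ps = docker.pose_set(ag)
        seq = "FWLK"
        ag_nodes = {p: r for p, r in zip(ag.structure.positions, ag.structure.residues)}
        for p in (0, ps.n_profiles // 2, ps.n_profiles - 1):
            positions = ps.profile_positions(p)
            e = 0.0
            for i, pos in enumerate(positions):
                for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                          (0, 0, 1), (0, 0, -1)):
                    q = tuple(pos + d)
                    if q in ag_nodes:
                        e += potential[seq[i], ag_nodes[q]]
                for j in range(i - 1):
                    if np.abs(positions[i] - positions[j]).sum() == 1:
                        e += potential[seq[i], seq[j]]
            assert profile_energy(seq, p, ps, ag, potential) == pytest.approx(e)

    def test_sequence_length_mismatch_rejected(self, potential):
        docker = Docker(potential, L=4, min_contacts=1)
        with pytest.raises(ValueError, match="length"):
            docker.binding_energy("AAAAA", l_antigen())

    def test_unbindable_antigen_rejected(self, potential):
        docker = Docker(potential, L=3, min_contacts=99)
        with pytest.raises(ValueError, match="unbindable"):
            docker.binding_energy("AAA", l_antigen())

    def test_cached_pose_set_reused_and_equal_to_fresh(self, potential):
        """Caching soundness: scoring through the cache equals independent
        re-enumeration for every sequence."""
        ag = tiny_antigen(3)
        cached = Docker(potential, L=4, min_contacts=2)
        seqs = random_bcr_panel(30, L=4, seed=23)
        through_cache = [cached.binding_energy(s, ag).energy for s in seqs]
        for s, e in zip(seqs, through_cache):
            fresh = Docker(potential, L=4, min_contacts=2)
            assert fresh.binding_energy(s, ag).energy == e
        assert len(cached._cache) == 1

    def test_batch_energies_match_single_calls(self, potential):
        ag = l_antigen()
        docker = Docker(potential, L=4, min_contacts=1)
        seqs = random_bcr_panel(15, L=4, seed=2)
        batch = docker.batch_energies(seqs, ag)
        single = [docker.binding_energy(s, ag).energy for s in seqs]
        np.testing.assert_allclose(batch, single)


def test_pose_set_cache_file_roundtrip(tmp_path, potential):
    """Pose sets survive a save/load cycle and refuse mismatched antigens."""
    from latticegc.docking import load_pose_set, save_pose_set

    ag = l_antigen()
    docker = Docker(potential, L=4, min_contacts=1)
    ps = docker.pose_set(ag)
    path = tmp_path / "poses.npz"
    save_pose_set(ps, path)
    back = load_pose_set(path)
    assert back.structure_key == ps.structure_key
    assert back.n_poses == ps.n_poses and back.n_profiles == ps.n_profiles
    fresh = Docker(potential, L=4, min_contacts=1)
    fresh.attach_pose_set(ag, back)
    seq = "FWLK"
    assert fresh.binding_energy(seq, ag).energy == \
        docker.binding_energy(seq, ag).energy
    other = Docker(potential, L=4, min_contacts=2)
    with pytest.raises(ValueError, match="does not match"):
        other.attach_pose_set(ag, back)
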