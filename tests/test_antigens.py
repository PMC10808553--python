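import numpy as np
import pytest
from scipy import stats

from latticegc.antigens import (Antigen, average_panel_energy,
                                build_antigen_set, classify_immunogenicity,
                                export_structure, generate_structure,
                                import_structure, randomize_residues)
from latticegc.docking import Docker
from latticegc.lattice import validate_chain


class TestGenerateStructure:
    def test_seeded_determinism(self):
        a = generate_structure(20, seed=5)
        b = generate_structure(20, seed=5)
        assert a == b
        assert generate_structure(20, seed=6) != a

    @pytest.mark.parametrize("n", [4, 12, 40])
    def test_valid_self_avoiding_chain(self, n):
        assert validate_chain(generate_structure(n, seed=1))

    def test_uniform_walk_end_to_end_grows_with_length(self):
        """compactness 0 is the plain self-avoiding walk: mean end-to-end
        distance increases with chain length (Monte Carlo)."""
        rng = np.random.default_rng(0)

        def mean_r2(n, walks=300):
            acc = 0.0
            for _ in range(walks):
                c = generate_structure(n, seed=int(rng.integers(2**31)),
                                       compactness=0.0)
                d = np.array(c.positions[-1]) - np.array(c.positions[0])
                acc += float(d @ d)
            return acc / walks

        assert mean_r2(8) < mean_r2(16) < mean_r2(32)

    def test_compactness_reduces_spread(self):
        def gyration(c):
            x = np.array(c.positions, dtype=float)
            return float(((x - x.mean(0)) ** 2).sum(1).mean())
        loose = np.mean([gyration(generate_structure(25, seed=s, compactness=0.0))
                         for s in range(30)])
        tight = np.mean([gyration(generate_structure(25, seed=s, compactness=3.0))
                         for s in range(30)])
        assert tight < loose

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_structure(3, seed=0)


class TestRandomizeResidues:
    def test_seeded_and_geometry_preserving(self):
        st = generate_structure(15, seed=2)
        a = randomize_residues(st, seed=9, identity="x")
        assert a.residues == randomize_residues(st, seed=9, identity="x").residues
        assert a.structure.positions == st.positions

    def test_residue_frequencies_uniform(self):
        """Uniform assignment over the 20 letters: chi-square not rejected
        at alpha = 0.01 over 10,000 draws."""
        st = generate_structure(10, seed=0)
        counts = np.zeros(20)
        letters = "CMFILVWYAGTSNQDEHRKP"
        for s in range(1000):
            for r in randomize_residues(st, seed=s, identity="x").residues:
                counts[letters.index(r)] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestImmunogenicityClasses:
    @pytest.mark.parametrize("energy, label", [
        (-76.0, "A"), (-80.0, "A"),       # below -75: most immunogenic
        (-59.0, "H"), (-50.0, "H"),       # above -60: least immunogenic
        (-68.0, "D"),                      # 2.5-kT bins from -75
        (-74.0, "B"), (-71.0, "C"), (-66.0, "E"), (-63.0, "F"), (-61.0, "G"),
    ])
    def test_binning(self, energy, label):
        assert classify_immunogenicity(energy) == label

    @pytest.mark.parametrize("boundary, label", [
        (-75.0, "B"), (-72.5, "C"), (-70.0, "D"), (-67.5, "E"),
        (-65.0, "F"), (-62.5, "G"), (-60.0, "H"),
    ])
    def test_boundaries_fall_right(self, boundary, label):
        assert classify_immunogenicity(boundary) == label

    def test_every_finite_energy_maps_to_one_class(self):
        for e in np.linspace(-100, -40, 241):
            assert classify_immunogenicity(float(e)) in "ABCDEFGH"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_immunogenicity(float("nan"))


class TestPanelEnergy:
    def test_single_sequence_panel(self, bundle):
        e = bundle.docker.binding_energy("FWLKC", bundle.tiny).energy
        assert average_panel_energy(bundle.tiny, ["FWLKC"], bundle.docker) == e

    def test_mean_equals_hand_sum(self, bundle):
        panel = bundle.panel[:10]
        singles = [bundle.docker.binding_energy(s, bundle.tiny).energy
                   for s in panel]
        assert average_panel_energy(bundle.tiny, panel, bundle.docker) == \
            pytest.approx(sum(singles) / 10)

    def test_empty_panel_rejected(self, bundle):
        with pytest.raises(ValueError):
            average_panel_energy(bundle.tiny, [], bundle.docker)

    def test_larger_panels_tighten_the_mean_estimate(self, bundle):
        """The spread of panel-mean estimates shrinks roughly as 1/sqrt(n):
        a modest panel already proxies a much larger repertoire."""
        from latticegc.repertoire import random_bcr_panel

        def spread(panel_size, n_panels=25):
            means = [
                average_panel_energy(
                    bundle.hi,
                    random_bcr_panel(panel_size, L=bundle.docker.L,
                                     seed=1000 * panel_size + i),
                    bundle.docker)
                for i in range(n_panels)]
            return np.std(means)

        s_small, s_large = spread(10), spread(40)
        ratio = s_small / s_large    # expected ~ sqrt(40/10) = 2
        assert 1.2 < ratio < 3.5


class TestAntigenSet:
    @pytest.mark.parametrize("k, per", [(1, 3000), (2, 1500), (5, 600)])
    def test_equal_dose_split(self, k, per):
        ags = [Antigen(generate_structure(6, seed=i), f"D{i}") for i in range(k)]
        s = build_antigen_set(ags, total_dose=3000)
        assert s.per_domain_dose == per

    def test_empty_and_duplicate_rejected(self):
        with pytest.raises(ValueError):
            build_antigen_set([])
        ag = Antigen(generate_structure(6, seed=0), "D")
        with pytest.raises(ValueError, match="duplicate"):
            build_antigen_set([ag, ag])


class TestStructureIO:
    def test_export_import_roundtrip(self, tmp_path, bundle):
        path = tmp_path / "ag.txt"
        export_structure(bundle.tiny, path)
        back = import_structure(path, identity=bundle.tiny.identity)
        assert back.structure == bundle.tiny.structure

    def test_duplicate_node_error_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 C 0 0 0\n1 W 1 0 0\n2 H 0 0 0\n")
        with pytest.raises(ValueError, match="line 3"):
            import_structure(path)
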