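import numpy as np
import pytest
from scipy import stats

from latticegc.antigens import build_antigen_set
from latticegc.lattice import AMINO_ACIDS
from latticegc.repertoire import (generate_founder_pool, mutate,
                                  random_bcr_panel, read_pool_fasta,
                                  write_pool_fasta)


class TestRandomPanel:
    def test_seeded_determinism(self):
        assert random_bcr_panel(200, L=9, seed=1) == random_bcr_panel(200, L=9, seed=1)
        assert random_bcr_panel(1, L=9, seed=1) != random_bcr_panel(1, L=9, seed=2)

    def test_single_sequence(self):
        panel = random_bcr_panel(1, L=9, seed=0)
        assert len(panel) == 1 and len(panel[0]) == 9

    def test_per_position_frequencies_uniform(self):
        panel = random_bcr_panel(20000, L=5, seed=3)
        for pos in range(5):
            counts = np.array([sum(1 for s in panel if s[pos] == aa)
                               for aa in AMINO_ACIDS])
            _, p = stats.chisquare(counts)
            assert p > 0.01

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            random_bcr_panel(0)


class TestMutate:
    def test_p_zero_identity(self):
        rng = np.random.default_rng(0)
        seq = "AWHKLMQRC"
        assert mutate(seq, 0.0, rng) == (seq, 0)

    def test_p_one_changes_every_position(self):
        rng = np.random.default_rng(0)
        seq = "AWHKLMQRC"
        out, n = mutate(seq, 1.0, rng)
        assert n == len(seq)
        assert all(a != b for a, b in zip(seq, out))

    def test_length_and_alphabet_preserved(self):
        rng = np.random.default_rng(5)
        seq = "AWHKL"
        for _ in range(200):
            seq, _ = mutate(seq, 0.3, rng)
            assert len(seq) == 5
            assert set(seq) <= set(AMINO_ACIDS)

    def test_replacement_count_is_binomial(self):
        """n_changes ~ Binomial(L, p): chi-square goodness of fit over
        10^5 draws at alpha = 0.01."""
        rng = np.random.default_rng(11)
        L, p, n = 9, 0.055, 100_000
        counts = np.bincount([mutate("A" * L, p, rng)[1] for _ in range(n)],
                             minlength=L + 1)
        expected = n * np.array([stats.binom.pmf(k, L, p) for k in range(L + 1)])
        keep = expected >= 5
        chi2 = (((counts[keep] - expected[keep]) ** 2) / expected[keep]).sum()
        chi2 += (counts[~keep].sum() - expected[~keep].sum()) ** 2 / expected[~keep].sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.01

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            mutate("AAA", 1.5, np.random.default_rng(0))


class TestFounderPool:
    def test_quota_and_affinity_floor(self, bundle):
        """Every founder meets the affinity floor to its assigned antigen,
        re-verified post hoc; counts split equally."""
        pool = bundle.pool
        cfg, docker = bundle.config, bundle.docker
        assert pool.total == cfg.founder_pool_total
        by_id = {a.identity: a for a in (bundle.hi, bundle.lo)}
        for agid, seqs in pool.sequences.items():
            assert len(seqs) == cfg.founder_pool_total // 2
            affs = np.exp((cfg.emax - docker.batch_energies(list(seqs), by_id[agid]))
                          / cfg.aff_c)
            assert (affs >= cfg.founder_min_affinity).all()

    def test_zero_floor_accepts_first_draws(self, bundle):
        agset = build_antigen_set([bundle.hi])
        pool = generate_founder_pool(agset, bundle.docker, pool_total=20,
                                     min_affinity=0.0, seed=4)
        raw = random_bcr_panel(20, L=bundle.docker.L,
                               rng=np.random.default_rng(4))
        assert list(pool.sequences["HI"]) == raw

    def test_remainder_policy_floor_division(self, bundle):
        agset = build_antigen_set([bundle.hi, bundle.lo])
        pool = generate_founder_pool(agset, bundle.docker, pool_total=9,
                                     min_affinity=0.0, seed=1)
        assert [len(v) for v in pool.sequences.values()] == [4, 4]

    def test_unreachable_floor_fails_with_best_affinity(self, bundle):
        agset = build_antigen_set([bundle.lo])
        with pytest.raises(RuntimeError, match="best affinity"):
            generate_founder_pool(agset, bundle.docker, pool_total=10,
                                  min_affinity=1e6, seed=0, max_attempts=2000)

    def test_injected_founders_face_floor(self, bundle):
        agset = build_antigen_set([bundle.hi])
        good = bundle.pool.sequences["HI"][0]
        pool = generate_founder_pool(agset, bundle.docker, pool_total=10,
                                     min_affinity=bundle.config.founder_min_affinity,
                                     seed=2, injected={"HI": [good]})
        assert pool.sequences["HI"][0] == good
        with pytest.raises(ValueError, match="injected"):
            generate_founder_pool(agset, bundle.docker, pool_total=10,
                                  min_affinity=1e6, seed=2,
                                  injected={"HI": [good]})

    def test_fasta_roundtrip(self, tmp_path, bundle):
        path = tmp_path / "pool.fasta"
        write_pool_fasta(bundle.pool, path)
        back = read_pool_fasta(path, min_affinity=bundle.pool.min_affinity)
        assert back.sequences == bundle.pool.sequences
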