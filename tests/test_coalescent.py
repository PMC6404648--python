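"""Coalescent engine: genealogies, mutation conditioning, structure, ARG."""

import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from pinepop.coalescent import (
    mutate_infinite_sites,
    simulate_genealogy,
    simulate_island,
    simulate_split,
    simulate_with_recombination,
)
from pinepop.differentiation import per_site_fst
from pinepop.diversity import harmonic_a


class TestGenealogy:
    @pytest.mark.parametrize("n,expect", [(2, 0.5), (10, 0.9)])
    def test_expected_tmrca(self, n, expect):
        rng = np.random.default_rng(n)
        reps = 4000
        tm = np.array([simulate_genealogy(n, rng).tmrca for _ in range(reps)])
        se = tm.std() / math.sqrt(reps)
        assert abs(tm.mean() - expect) < 3 * se

    def test_total_length_expectation(self):
        rng = np.random.default_rng(3)
        n, reps = 10, 4000
        tl = np.array([simulate_genealogy(n, rng).total_length
                       for _ in range(reps)])
        se = tl.std() / math.sqrt(reps)
        assert abs(tl.mean() - harmonic_a(n - 1)) < 3 * se

    def test_determinism(self):
        g1 = simulate_genealogy(8, seed=99)
        g2 = simulate_genealogy(8, seed=99)
        assert np.array_equal(g1.parent, g2.parent)
        assert np.allclose(g1.time, g2.time)

    def test_newick_parses(self):
        import io as _io

        from Bio import Phylo

        g = simulate_genealogy(6, seed=4)
        tree = Phylo.read(_io.StringIO(g.to_newick()), "newick")
        assert tree.count_terminals() == 6


class TestMutation:
    def test_expected_S(self):
        rng = np.random.default_rng(10)
        n, theta, reps = 10, 5.0, 5000
        S = np.array([
            mutate_infinite_sites(simulate_genealogy(n, rng), 10_000,
                                  theta=theta, seed=rng).S
            for _ in range(reps)
        ])
        expect = theta * harmonic_a(n - 1)
        se = S.std() / math.sqrt(reps)
        assert abs(S.mean() - expect) < 3 * se

    def test_fixed_s_conditioning(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            sim = mutate_infinite_sites(simulate_genealogy(6, rng), 100,
                                        S=7, seed=rng)
            assert sim.S == 7

    def test_fixed_s_zero_monomorphic(self):
        sim = mutate_infinite_sites(simulate_genealogy(4, seed=2), 100,
                                    S=0, seed=3)
        assert sim.matrix.shape == (4, 0)

    def test_infinite_sites_violation(self):
        with pytest.raises(ValueError):
            mutate_infinite_sites(simulate_genealogy(4, seed=2), 5, S=7, seed=3)

    def test_exactly_one_conditioning_mode(self):
        g = simulate_genealogy(4, seed=2)
        with pytest.raises(ValueError):
            mutate_infinite_sites(g, 100, theta=1.0, S=3)


class TestIsland:
    def test_panmixia_limit_large_m(self):
        rng = np.random.default_rng(6)
        counts = []
        for _ in range(300):
            g = simulate_island(10, 200.0, [10, 10], seed=rng)
            sim = mutate_infinite_sites(g, 100, S=1, seed=rng)
            col = sim.matrix[:, 0]
            counts.append([col[:10].sum(), col[10:].sum()])
        fst, _ = per_site_fst(np.array(counts, float), np.array([10., 10.]))
        assert abs(np.nanmean(fst)) < 0.02

    def test_m_zero_multi_deme_errors(self):
        with pytest.raises(ValueError):
            simulate_island(5, 0.0, [5, 5], seed=1)

    def test_single_deme_sampling_strong_migration_limit(self):
        """Sampling one deme of a 2-deme island at strong migration gives the
        panmictic S distribution of the doubled (2N-total) population.

        (With per-deme size N, an island model is a population of total size
        dN: one-deme sampling is *not* equivalent to a panmictic deme of size
        N — the correct marginalization is to the pooled population.)
        """
        rng = np.random.default_rng(12)
        S_island = []
        S_pan = []
        for _ in range(600):
            gi = simulate_island(2, 400.0, {0: 8}, seed=rng)
            S_island.append(mutate_infinite_sites(gi, 100_000, theta=4.0,
                                                  seed=rng).S)
            gp = simulate_genealogy(8, rng)
            S_pan.append(mutate_infinite_sites(gp, 100_000, theta=8.0,
                                               seed=rng).S)
        assert ks_2samp(S_island, S_pan).pvalue > 0.01

    def test_fast_backend_matches_reference(self):
        """Compiled island SNP simulator agrees with the pure-Python engine."""
        from pinepop.outliers import simulate_island_snps

        fst_f, he_f = simulate_island_snps(20, 5.0, [12, 12], 1500, seed=5)
        fst_n, he_n = simulate_island_snps(20, 5.0, [12, 12], 300, seed=6,
                                           backend="native")
        assert ks_2samp(fst_f[~np.isnan(fst_f)],
                        fst_n[~np.isnan(fst_n)]).pvalue > 0.01
        assert ks_2samp(he_f[~np.isnan(he_f)],
                        he_n[~np.isnan(he_n)]).pvalue > 0.01


class TestSplit:
    def _sharing(self, T, theta, rng):
        from pinepop.datamodel import LocusAlignment
        from pinepop.divergence import polymorphism_sharing

        g = simulate_split([(T, 0, 1)], {0: 8, 1: 8}, seed=rng)
        sim = mutate_infinite_sites(g, 5000, theta=theta, seed=rng)
        full = np.full((16, 5000), "A", dtype="U1")
        if sim.S:
            full[:, sim.positions] = np.where(sim.matrix == 1, "T", "A")
        aln = LocusAlignment("s", [f"s{i}" for i in range(16)],
                             ["".join(r) for r in full])
        return polymorphism_sharing(
            aln, [f"s{i}" for i in range(8)], [f"s{i}" for i in range(8, 16)])

    def test_deep_split_no_shared(self):
        rng = np.random.default_rng(14)
        shared = fixed = others = 0
        for _ in range(30):
            c = self._sharing(100.0, 10.0, rng)
            shared += c["shared"]
            fixed += c["fixed"]
            others += c["exclusive_1"] + c["exclusive_2"]
        assert shared / (shared + others) < 0.01
        assert fixed > 0

    def test_recent_split_mostly_shared(self):
        rng = np.random.default_rng(15)
        shared = others = 0
        for _ in range(30):
            c = self._sharing(0.01, 10.0, rng)
            shared += c["shared"]
            others += c["exclusive_1"] + c["exclusive_2"]
        assert shared / (shared + others) > 0.5

    def test_single_tip_reduces_to_panmictic(self):
        rng = np.random.default_rng(16)
        S_split = []
        S_pan = []
        for _ in range(800):
            g = simulate_split([(0.5, 0, 1)], {0: 8, 1: 0}, seed=rng)
            S_split.append(mutate_infinite_sites(g, 10_000, theta=4.0,
                                                 seed=rng).S)
            S_pan.append(mutate_infinite_sites(simulate_genealogy(8, rng),
                                               10_000, theta=4.0, seed=rng).S)
        assert ks_2samp(S_split, S_pan).pvalue > 0.01


class TestRecombination:
    def test_zero_rho_single_tree(self):
        sim = simulate_with_recombination(10, theta=5.0, rho=0.0, L=1000,
                                          seed=7)
        assert sim.genealogy.n == 10

    def test_determinism(self):
        a = simulate_with_recombination(10, theta=5.0, rho=5.0, L=1000, seed=8)
        b = simulate_with_recombination(10, theta=5.0, rho=5.0, L=1000, seed=8)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.positions, b.positions)

    def test_ld_decays_with_distance_at_high_rho(self):
        from pinepop.datamodel import LocusAlignment, build_variant_table
        from pinepop.linkage import pairwise_r2

        near, far = [], []
        L = 1000
        for rep in range(40):
            sim = simulate_with_recombination(20, theta=10.0, rho=40.0, L=L,
                                              seed=200 + rep)
            if sim.S < 4:
                continue
            full = np.full((20, L), "A", dtype="U1")
            pos = np.clip(sim.positions, 0, L - 1)
            full[:, pos] = np.where(sim.matrix == 1, "T", "A")
            aln = LocusAlignment("r", [f"s{i}" for i in range(20)],
                                 ["".join(r) for r in full])
            for p in pairwise_r2(build_variant_table(aln)):
                (near if p.distance < L / 4 else far).append(p.r2)
        assert np.mean(near) > np.mean(far)

    def test_guard(self):
        with pytest.raises(ValueError):
            simulate_with_recombination(40, theta=1.0, rho=1.0, L=100)
        with pytest.raises(ValueError):
            simulate_with_recombination(10, theta=1.0, rho=100.0, L=100)


class TestMsprimeCrossCheck:
    def test_expected_s_agrees_with_msprime(self):
        """Independent simulator oracle: S distribution from msprime under
        the same scaling matches the in-package engine."""
        import msprime

        rng = np.random.default_rng(20)
        n, theta, L = 12, 6.0, 100_000
        S_own = [
            mutate_infinite_sites(simulate_genealogy(n, rng), L, theta=theta,
                                  seed=rng).S
            for _ in range(1500)
        ]
        S_ms = []
        reps = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=0.5, sequence_length=L,
            num_replicates=1500, random_seed=77)
        for ts in reps:
            mts = msprime.sim_mutations(
                ts, rate=theta / L, discrete_genome=False, random_seed=None)
            S_ms.append(mts.num_sites)
        assert ks_2samp(S_own, S_ms).pvalue > 0.01
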