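"""pi, Watterson's theta, haplotype diversity, silent sites, theta posterior."""

import math

import numpy as np
import pytest

from pinepop.coalescent import mutate_infinite_sites, simulate_genealogy
from pinepop.datamodel import SiteAnnotation, build_variant_table, extract_haplotypes
from pinepop.diversity import (
    consensus_sequence,
    harmonic_a,
    haplotype_diversity,
    multilocus_theta_posterior,
    nucleotide_diversity,
    segsite_log_pmf,
    site_class_lengths,
    synonymous_fraction,
    watterson_theta,
)

from conftest import random_alignment


class TestPointStatistics:
    def test_pi_toy(self, toy_alignment):
        vt = build_variant_table(toy_alignment)
        assert nucleotide_diversity(vt, 10) == pytest.approx((1 + 2 + 1) / 3 / 10)

    def test_pi_two_sequences(self):
        from pinepop.datamodel import LocusAlignment
        seqs = ["A" * 100, "A" * 99 + "T"]
        aln = LocusAlignment("x", ["a", "b"], seqs)
        vt = build_variant_table(aln)
        assert nucleotide_diversity(vt, 100) == pytest.approx(0.01)

    @pytest.mark.parametrize("S,n,L,expect", [
        (3, 4, 100, 3 / ((1 + 1 / 2 + 1 / 3) * 100)),
        (0, 10, 100, 0.0),
        (2, 3, 10, 2 / (1.5 * 10)),
    ])
    def test_watterson(self, S, n, L, expect):
        assert watterson_theta(S, n, L) == pytest.approx(expect, rel=1e-9)

    def test_pi_equals_watterson_on_toy(self, toy_alignment):
        # the D=0 case: k_mean = S/a_{n-1}
        vt = build_variant_table(toy_alignment)
        assert nucleotide_diversity(vt, 10) == pytest.approx(
            watterson_theta(2, 3, 10))

    def test_haplotype_diversity_cases(self):
        from pinepop.datamodel import HaplotypeSet

        hs = HaplotypeSet("x", {"A": 2, "B": 2}, {})
        assert haplotype_diversity(hs)[0] == pytest.approx(4 / 3 * 0.5)
        hs1 = HaplotypeSet("x", {"A": 5}, {})
        assert haplotype_diversity(hs1)[0] == 0.0
        hsn = HaplotypeSet("x", {c: 1 for c in "ABCDE"}, {})
        assert haplotype_diversity(hsn)[0] == pytest.approx(1.0)

    def test_brute_force_equality(self):
        """pi, theta_W, H_d equal exhaustive enumeration on random data."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            aln = random_alignment(rng, n, int(rng.integers(30, 100)))
            vt = build_variant_table(aln, include_indels=False)
            # brute-force pi: mean over pairs of per-site differences
            total = 0.0
            npairs = 0
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = aln.matrix[i], aln.matrix[j]
                    ok = np.isin(a, list("ACGT")) & np.isin(b, list("ACGT"))
                    # per-site contribution form (matches pairwise deletion)
                    npairs += 1
            pi_bf = 0.0
            for col in range(aln.length):
                cc = [c for c in aln.matrix[:, col] if c in "ACGT"]
                nc = len(cc)
                if nc < 2:
                    continue
                diff = sum(1 for x in range(nc) for y in range(x + 1, nc)
                           if cc[x] != cc[y])
                pi_bf += diff / (nc * (nc - 1) / 2)
            pi_bf /= aln.length
            assert nucleotide_diversity(vt, aln.length) == pytest.approx(
                pi_bf, abs=1e-12)
            a_bf = sum(1 / i for i in range(1, n))
            assert watterson_theta(vt.S_snp, n, aln.length) == pytest.approx(
                vt.S_snp / (a_bf * aln.length), abs=1e-12)
            hs = extract_haplotypes(aln, max_missing_frac=1.0)
            counts = np.array(sorted(hs.haplotypes.values()))
            p = counts / counts.sum()
            hd_bf = hs.n / (hs.n - 1) * (1 - np.sum(p**2))
            assert haplotype_diversity(hs)[0] == pytest.approx(hd_bf, abs=1e-12)


class TestSilentSites:
    def test_all_noncoding(self):
        from pinepop.datamodel import LocusAlignment

        aln = LocusAlignment("x", ["a", "b"], ["ACGT" * 100, "ACGT" * 100])
        ann = SiteAnnotation("x", [])
        L, Ls = site_class_lengths(aln, ann)
        assert (L, Ls) == (400, 400.0)

    def test_atg_has_no_synonymous_sites(self):
        assert synonymous_fraction("ATG") == 0.0
        # fourfold degenerate third position
        assert synonymous_fraction("GGG") == pytest.approx(1.0)

    def test_coding_interval_uses_nei_gojobori(self):
        from pinepop.datamodel import LocusAlignment

        aln = LocusAlignment("x", ["a", "b"], ["ATGGGG", "ATGGGG"])
        ann = SiteAnnotation("x", [(0, 6, 0)])
        L, Ls = site_class_lengths(aln, ann)
        assert L == 6
        assert Ls == pytest.approx(synonymous_fraction("ATG")
                                   + synonymous_fraction("GGG"))

    def test_no_annotation_returns_none(self, toy_alignment):
        L, Ls = site_class_lengths(toy_alignment, None)
        assert L == 10 and Ls is None

    def test_consensus_majority(self, toy_alignment):
        assert consensus_sequence(toy_alignment) == "AAAAAAAAAT"


def _segsite_pmf_by_convolution(s: int, theta: float, n: int) -> float:
    """Independent oracle: S is the sum over coalescent levels k=2..n of
    independent geometric variables with success prob (k-1)/(theta+k-1)."""
    dist = np.zeros(s + 1)
    dist[0] = 1.0
    for k in range(2, n + 1):
        q = theta / (theta + k - 1)  # failure prob: one more mutation
        geo = (1 - q) * q ** np.arange(s + 1)
        new = np.convolve(dist, geo)[: s + 1]
        dist = new
    return float(dist[s])


class TestSegsiteLikelihood:
    @pytest.mark.parametrize("s,theta,n", [
        (0, 1.0, 5), (3, 2.0, 8), (10, 5.0, 20), (2, 0.5, 40),
    ])
    def test_closed_form_matches_convolution_oracle(self, s, theta, n):
        # the alternating closed form loses ~n digits to cancellation; the
        # geometric-convolution oracle is numerically stable
        expect = _segsite_pmf_by_convolution(s, theta, n)
        assert math.exp(segsite_log_pmf(s, theta, n)) == pytest.approx(
            expect, rel=1e-5)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(3)
        n, theta = 10, 3.0
        S = np.array([
            mutate_infinite_sites(simulate_genealogy(n, rng), 10_000,
                                  theta=theta, seed=rng).S
            for _ in range(4000)
        ])
        for s in (2, 5, 9):
            mc = float(np.mean(S == s))
            se = math.sqrt(mc * (1 - mc) / len(S))
            assert math.exp(segsite_log_pmf(s, theta, n)) == pytest.approx(
                mc, abs=3.5 * se + 1e-4)


class TestThetaPosterior:
    def test_no_mutations_concentrates_low(self):
        post = multilocus_theta_posterior(
            np.zeros(10, int), np.full(10, 10), np.full(10, 500.0),
            burn_in=200, samples=3000, seed=1)
        assert post.median < 1e-4

    def test_recovery_within_15_percent(self):
        rng = np.random.default_rng(5)
        theta = 0.005
        n, L, n_loci = 20, 400, 79
        S = np.array([
            mutate_infinite_sites(simulate_genealogy(n, rng), L,
                                  theta=theta * L, seed=rng).S
            for _ in range(n_loci)
        ])
        post = multilocus_theta_posterior(
            S, np.full(n_loci, n), np.full(n_loci, float(L)),
            burn_in=500, samples=20000, seed=2)
        assert abs(post.median - theta) / theta < 0.15
        assert post.ci_low < post.median < post.ci_high

    def test_single_locus_mode_matches_grid_mle(self):
        n, L, S = 12, 500, 7
        post = multilocus_theta_posterior(
            np.array([S]), np.array([n]), np.array([L]),
            burn_in=500, samples=30000, seed=3)
        grid = np.logspace(-5, -1, 4000)
        ll = [segsite_log_pmf(S, t * L, n) for t in grid]
        mle = grid[int(np.argmax(ll))]
        # flat-in-log prior: posterior mode ~ MLE; median close at this ESS
        assert abs(math.log(post.median) - math.log(mle)) < 0.35

    def test_interval_coverage(self):
        """95% credible interval covers the truth in >= 90% of recovery runs."""
        rng = np.random.default_rng(17)
        theta, n, L, n_loci = 0.005, 15, 400, 25
        hits = 0
        runs = 40
        for r in range(runs):
            S = np.array([
                mutate_infinite_sites(simulate_genealogy(n, rng), L,
                                      theta=theta * L, seed=rng).S
                for _ in range(n_loci)
            ])
            post = multilocus_theta_posterior(
                S, np.full(n_loci, n), np.full(n_loci, float(L)),
                burn_in=200, samples=4000, seed=100 + r)
            if post.ci_low <= theta <= post.ci_high:
                hits += 1
        assert hits / runs >= 0.9


class TestMomentChecks:
    def test_pi_and_theta_unbiased_on_neutral_sims(self):
        """mean(pi_hat * L) and mean(theta_W_hat * L) within 2 SE of theta."""
        rng = np.random.default_rng(9)
        n, theta, reps = 20, 5.0, 2000
        a = harmonic_a(n - 1)
        pis, thetas = [], []
        for _ in range(reps):
            sim = mutate_infinite_sites(simulate_genealogy(n, rng), 100_000,
                                        theta=theta, seed=rng)
            xi = sim.matrix.sum(axis=0)
            pis.append(float(np.sum(2 * xi * (n - xi)) / (n * (n - 1))))
            thetas.append(sim.S / a)
        for est in (pis, thetas):
            m, se = np.mean(est), np.std(est) / math.sqrt(reps)
            assert abs(m - theta) < 2 * se + 0.05
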