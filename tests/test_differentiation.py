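"""AMOVA, pairwise and per-SNP F_ST, S_nn, PCoA and the haplotype network."""

import numpy as np
import pytest
from scipy.stats import kstest

from pinepop.differentiation import (
    amova,
    haplotype_msn,
    pairwise_difference_matrix,
    pairwise_fst,
    pcoa,
    per_site_fst,
    snn,
    snn_statistic,
)


def _binary_distance(rows: list[str]) -> np.ndarray:
    mat = np.array([list(r) for r in rows], dtype="U1")
    return pairwise_difference_matrix(mat)


class TestAmova:
    def test_fixed_haplotypes_phi_one(self):
        D = _binary_distance(["AAAA"] * 4 + ["TTTT"] * 4)
        res = amova(D, ["p1"] * 4 + ["p2"] * 4, permutations=50, seed=1)
        assert res.phi["phi_st"] == pytest.approx(1.0)

    def test_two_level_matches_sums_of_squares_oracle(self):
        """Components equal an independent direct sums-of-squares
        computation (Excoffier-style) on a random instance."""
        rng = np.random.default_rng(2)
        n_per = [5, 7, 4]
        rows = []
        pops = []
        for pi, m in enumerate(n_per):
            centre = rng.choice(list("ACGT"), size=30)
            for _ in range(m):
                row = centre.copy()
                nm = rng.integers(0, 5)
                idx = rng.choice(30, size=nm, replace=False)
                row[idx] = [rng.choice(list("ACGT")) for _ in range(nm)]
                rows.append("".join(row))
                pops.append(f"p{pi}")
        D = _binary_distance(rows)
        res = amova(D, pops, permutations=10, seed=3)
        # oracle: direct SSD computation
        D2 = D * D
        N = len(pops)
        P = len(n_per)
        idx_of = {}
        for i, p in enumerate(pops):
            idx_of.setdefault(p, []).append(i)
        ssd_t = D2.sum() / (2 * N)
        ssd_wp = sum(D2[np.ix_(ii, ii)].sum() / (2 * len(ii))
                     for ii in idx_of.values())
        ssd_ap = ssd_t - ssd_wp
        ms_wp = ssd_wp / (N - P)
        ms_ap = ssd_ap / (P - 1)
        n_prime = (N - sum(m * m for m in n_per) / N) / (P - 1)
        sigma_w = ms_wp
        sigma_a = (ms_ap - ms_wp) / n_prime
        assert res.components["within_pops"] == pytest.approx(sigma_w, abs=1e-10)
        assert res.components["among_pops"] == pytest.approx(sigma_a, abs=1e-10)
        assert res.phi["phi_st"] == pytest.approx(
            sigma_a / (sigma_a + sigma_w), abs=1e-10)

    def test_three_level_hand_worked(self):
        """Six samples, two groups of two populations: hand-checkable sums."""
        rows = ["AAAA", "AAAT", "AATT", "ATTT", "TTTT", "TTTA"]
        pops = ["p1", "p1", "p2", "p2", "p3", "p3"]
        grps = ["g1", "g1", "g1", "g1", "g2", "g2"]
        D = _binary_distance(rows)
        res = amova(D, pops, grps, permutations=20, seed=4)
        D2 = D * D
        ssd_t = D2.sum() / 12
        ssd_wp = sum(D2[i, j] ** 0 * D2[i, j] / 2
                     for i, j in [(0, 1), (2, 3), (4, 5)])  # n_p=2 blocks
        # within-group SSDs
        g1 = [0, 1, 2, 3]
        ssd_wg = D2[np.ix_(g1, g1)].sum() / 8 + D2[np.ix_([4, 5], [4, 5])].sum() / 4
        ssd_ag = ssd_t - ssd_wg
        ssd_ap = ssd_wg - ssd_wp
        ms_wp = ssd_wp / 3
        ms_ap = ssd_ap / 1
        ms_ag = ssd_ag / 1
        # coefficients for equal pop sizes 2, groups of 4 and 2 samples
        sum_np2_over_ng = (4 + 4) / 4 + 4 / 2
        n1 = (6 - sum_np2_over_ng) / 1
        n2 = (sum_np2_over_ng - (4 + 4 + 4) / 6) / 1
        n3 = (6 - (16 + 4) / 6) / 1
        sw = ms_wp
        sb = (ms_ap - sw) / n1
        sa = (ms_ag - sw - n2 * sb) / n3
        assert res.components["within_pops"] == pytest.approx(sw, abs=1e-10)
        assert res.components["among_pops_within_groups"] == pytest.approx(
            sb, abs=1e-10)
        assert res.components["among_groups"] == pytest.approx(sa, abs=1e-10)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_null_permutation_p_uniform(self):
        """Under exchangeable labels the permutation p-value is uniform."""
        rng = np.random.default_rng(5)
        pvals = []
        for rep in range(120):
            mat = rng.choice(list("AT"), size=(16, 25))
            D = pairwise_difference_matrix(mat)
            labels = ["a"] * 8 + ["b"] * 8
            res = amova(D, labels, permutations=99, seed=int(rng.integers(2**31)))
            pvals.append(res.p_values["phi_st"])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestPairwiseFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(6)
        mat = rng.choice(list("AT"), size=(20, 40))
        D = pairwise_difference_matrix(mat)
        fst, _ = pairwise_fst(D, ["a"] * 10 + ["b"] * 10, permutations=30,
                              seed=7)
        assert abs(fst.loc["a", "b"]) < 0.15

    def test_fixed_difference_is_one(self):
        D = _binary_distance(["AAAA"] * 3 + ["TTTT"] * 3)
        fst, p = pairwise_fst(D, ["a"] * 3 + ["b"] * 3, permutations=99, seed=8)
        assert fst.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] < 0.15

    def test_monotone_in_split_time(self):
        from pinepop.coalescent import mutate_infinite_sites, simulate_split

        rng = np.random.default_rng(9)
        means = []
        for T in (0.02, 0.2, 1.0):
            vals = []
            for _ in range(15):
                g = simulate_split([(T, 0, 1)], {0: 8, 1: 8}, seed=rng)
                sim = mutate_infinite_sites(g, 1000, theta=5.0, seed=rng)
                if sim.S < 2:
                    continue
                mat = np.where(sim.matrix == 1, "T", "A").astype("U1")
                D = pairwise_difference_matrix(mat)
                fst, _ = pairwise_fst(D, ["a"] * 8 + ["b"] * 8,
                                      permutations=5, seed=rng)
                vals.append(fst.loc["a", "b"])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestPerSiteFst:
    def test_equal_frequencies_zero(self):
        fst, he = per_site_fst(np.array([[5, 5]]), np.array([10, 10]))
        assert fst[0] == pytest.approx(0.0, abs=1e-9) or fst[0] < 0.01

    def test_fixed_difference_one(self):
        fst, _ = per_site_fst(np.array([[10, 0]]), np.array([10, 10]))
        assert fst[0] == pytest.approx(1.0)

    def test_matches_amova_machinery(self):
        """Closed-form per-SNP F_ST equals the full AMOVA on 0/1 haplotypes
        (deme1: 6A/4a, deme2: 2A/8a)."""
        rows = ["A"] * 6 + ["T"] * 4 + ["A"] * 2 + ["T"] * 8
        mat = np.array([[c] for c in rows], dtype="U1")
        D = pairwise_difference_matrix(mat)
        res = amova(D, ["d1"] * 10 + ["d2"] * 10, permutations=5, seed=1)
        fst, he = per_site_fst(np.array([[4, 8]]), np.array([10, 10]))
        assert fst[0] == pytest.approx(res.phi["phi_st"], abs=1e-10)

    def test_monomorphic_is_nan(self):
        fst, he = per_site_fst(np.array([[0, 0], [10, 10]]),
                               np.array([10, 10]))
        assert np.isnan(fst).all()


class TestSnn:
    def test_disjoint_groups(self):
        D = _binary_distance(["AAAA", "AAAT", "TTTT", "TTTA"])
        labels = np.array(["a", "a", "b", "b"])
        assert snn_statistic(D, labels) == pytest.approx(1.0)

    def test_hand_worked_tie_case(self):
        # distances: s0-s1=1, s0-s2=1 (tie), s1-s2=2, s3 far from all
        rows = ["AAAA", "AAAT", "AATA", "TTTT"]
        D = _binary_distance(rows)
        labels = np.array(["a", "a", "b", "b"])
        # s0: nn {s1,s2} tie -> 1/2; s1: nn s0 -> 1; s2: nn s0 -> 0;
        # s3: nn = nearest among others (distance 3 to s1,s2... compute)
        got = snn_statistic(D, labels)
        d3 = [np.sum(np.array(list(rows[3])) != np.array(list(r)))
              for r in rows[:3]]
        nn3 = np.array(["a", "a", "b"])[np.array(d3) == min(d3)]
        frac3 = np.mean(nn3 == "b")
        assert got == pytest.approx((0.5 + 1.0 + 0.0 + frac3) / 4)

    def test_random_labels_expectation_half(self):
        rng = np.random.default_rng(10)
        mat = rng.choice(list("ACGT"), size=(12, 30))
        D = pairwise_difference_matrix(mat)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        vals = [snn_statistic(D, labels[rng.permutation(12)])
                for _ in range(300)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.06)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(11)
        mat = rng.choice(list("ACGT"), size=(10, 20))
        D = pairwise_difference_matrix(mat)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        assert snn_statistic(D, labels) == snn_statistic(np.sqrt(D) + 2 * (D > 0),
                                                         labels)

    def test_permutation_p(self):
        D = _binary_distance(["AAAA"] * 3 + ["TTTT"] * 3)
        res = snn(D, ["a"] * 3 + ["b"] * 3, permutations=199, seed=12)
        assert res.snn == 1.0
        assert res.p_value < 0.1


class TestPcoa:
    def test_collinear_points(self):
        pts = np.array([0.0, 1.0, 3.0])
        D = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(D)
        axis1 = res.coordinates[:, 0]
        spacing = np.diff(np.sort(axis1))
        assert np.allclose(sorted(spacing), [1.0, 2.0], atol=1e-8)
        assert len(res.eigenvalues) == 1 or res.pct_variance[0] > 99.9

    def test_equilateral_simplex(self):
        D = np.ones((4, 4)) - np.eye(4)
        res = pcoa(D)
        assert np.allclose(res.eigenvalues, res.eigenvalues[0], atol=1e-10)

    def test_reconstructs_planar_distances(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(7, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(D)
        rec = res.coordinates[:, :2]
        D2 = np.linalg.norm(rec[:, None] - rec[None, :], axis=2)
        assert np.allclose(D, D2, atol=1e-8)

    def test_matches_skbio(self):
        """Independent oracle: scikit-bio's PCoA on the same matrix."""
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(14)
        pts = rng.normal(size=(9, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        mine = pcoa(D)
        ref = skbio_pcoa(D.astype(float))
        ref_eigs = np.array(ref.eigvals)[:len(mine.eigenvalues)]
        assert np.allclose(mine.eigenvalues, ref_eigs, atol=1e-6)
        for k in range(2):
            a = mine.coordinates[:, k]
            b = np.array(ref.samples.iloc[:, k])
            assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0, 1], [2, 0]]))


class TestHaplotypeNetwork:
    def test_unique_mst_chain(self):
        G = haplotype_msn(["AAA", "AAT", "ATT"])
        assert set(map(frozenset, G.edges)) == {frozenset({0, 1}),
                                                frozenset({1, 2})}

    def test_cominimal_triangle_retained(self):
        G = haplotype_msn(["AAB", "ABA", "BAA"])  # all pairs distance 2
        assert G.number_of_edges() == 3

    def test_total_weight_matches_networkx_mst(self):
        import itertools

        import networkx as nx

        rng = np.random.default_rng(15)
        haps = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(8)]
        haps = list(dict.fromkeys(haps))
        G = haplotype_msn(haps)
        K = nx.Graph()
        for i, j in itertools.combinations(range(len(haps)), 2):
            w = sum(a != b for a, b in zip(haps[i], haps[j]))
            K.add_edge(i, j, weight=w)
        ref = nx.minimum_spanning_tree(K)
        ref_w = sum(d["weight"] for _, _, d in ref.edges(data=True))
        # the MSN contains a spanning tree of exactly the MST weight: greedily
        # extract one via Kruskal restricted to MSN edges
        sub_w = sum(d["weight"] for _, _, d in
                    nx.minimum_spanning_tree(G).edges(data=True))
        assert sub_w == ref_w
        # and every MST edge weight class is represented
        assert nx.is_connected(G)
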