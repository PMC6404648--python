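"""Neutrality tests: Tajima's D, Fay & Wu's H, Ewens-Watterson, HKA,
multilocus and compound machinery."""

import itertools
import math

import numpy as np
import pytest

from pinepop.datamodel import build_variant_table, polarize_variants
from pinepop.diversity import harmonic_a, harmonic_b
from pinepop.neutrality import (
    CompoundTester,
    NullBank,
    ewens_watterson,
    fay_wu_h,
    fay_wu_h_value,
    hka_test,
    multilocus_tajima,
    sim_neutral_stats,
    tajima_d,
    tajima_d_value,
)


class TestTajimaD:
    def test_toy_is_zero(self, toy_alignment):
        vt = build_variant_table(toy_alignment)
        res = tajima_d(vt, reps=200, seed=1)
        assert res.statistic == 0.0

    def test_numerator_identity(self):
        # whenever k_mean = S/a_{n-1} the statistic vanishes
        for n, S in [(5, 4), (12, 9), (30, 20)]:
            k = S / harmonic_a(n - 1)
            assert tajima_d_value(S, n, k) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_at_zero_S(self):
        assert math.isnan(tajima_d_value(0, 10, 0.0))

    def test_matches_straight_formula(self):
        """D equals an independent straight-from-the-paper reimplementation."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(4, 40))
            S = int(rng.integers(1, 60))
            k = float(rng.uniform(0, S))
            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            var = c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1)
            if var <= 0:
                continue
            expect = (k - S / a1) / math.sqrt(var)
            assert tajima_d_value(S, n, k) == pytest.approx(expect, abs=1e-10)


class TestFayWuH:
    def test_toy_unnormalized(self, toy_alignment):
        vt = polarize_variants(build_variant_table(toy_alignment),
                               np.array(list("AAAAAAAAAA")))
        res = fay_wu_h(vt, reps=200, seed=1)
        assert res.extra["unnormalized"] == pytest.approx(-1 / 3)

    def test_n2_identity(self):
        # at n=2 every derived allele is a singleton: theta_pi == theta_H
        _, unnorm = fay_wu_h_value(np.array([1, 1, 1]), 2)
        assert unnorm == pytest.approx(0.0, abs=1e-12)

    def test_matches_straight_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            S = int(rng.integers(1, 30))
            xi = rng.integers(1, n, size=S)
            tp = sum(2 * x * (n - x) for x in xi) / (n * (n - 1))
            tl = sum(xi) / (n - 1)
            an = sum(1 / i for i in range(1, n))
            bn = sum(1 / i**2 for i in range(1, n))
            bn1 = sum(1 / i**2 for i in range(1, n + 1))
            tw = S / an
            tsq = S * (S - 1) / (an**2 + bn)
            var = ((n - 2) / (6 * (n - 1)) * tw
                   + (18 * n**2 * (3 * n + 2) * bn1
                      - (88 * n**3 + 9 * n**2 - 13 * n + 6))
                   / (9 * n * (n - 1) ** 2) * tsq)
            expect = (tp - tl) / math.sqrt(var)
            got, _ = fay_wu_h_value(xi, n)
            assert got == pytest.approx(expect, abs=1e-10)


def _ewens_conditional_pmf(n: int, k: int) -> dict[tuple, float]:
    """Exact ESF conditional on k by enumeration (theta-free) — oracle."""
    weights = {}
    for part in _partitions(n, k):
        w = math.factorial(n)
        for size, mult in _multiplicity(part).items():
            w /= (size ** mult) * math.factorial(mult)
        weights[part] = w
    total = sum(weights.values())
    return {p: w / total for p, w in weights.items()}


def _partitions(n, k, mx=None):
    mx = mx or n
    if k == 1:
        if n <= mx:
            yield (n,)
        return
    for first in range(min(n - k + 1, mx), 0, -1):
        for rest in _partitions(n - first, k - 1, first):
            yield (first,) + rest


def _multiplicity(part):
    out = {}
    for p in part:
        out[p] = out.get(p, 0) + 1
    return out


class TestEwensWatterson:
    def test_single_haplotype(self):
        res = ewens_watterson([5], reps=200, seed=1)
        assert res.statistic == 1.0
        assert res.extra.get("degenerate")

    def test_all_distinct_minimum(self):
        res = ewens_watterson([1, 1, 1], reps=400, seed=2)
        assert res.statistic == pytest.approx(1 / 3)
        assert res.p_one_sided == 1.0

    def test_counts_31(self):
        res = ewens_watterson([3, 1], reps=4000, seed=3)
        assert res.statistic == pytest.approx(0.625)
        # exact conditional: P(F >= 0.625 | n=4, k=2) = P({3,1}) = 8/11
        pmf = _ewens_conditional_pmf(4, 2)
        exact = sum(p for part, p in pmf.items()
                    if sum((c / 4) ** 2 for c in part) >= 0.625)
        assert res.p_one_sided == pytest.approx(exact, abs=0.03)

    def test_null_matches_enumeration(self):
        """CRP-rejection null frequencies equal the exact conditional ESF."""
        from pinepop.neutrality import _crp_sample_F, _ewens_theta_for_k

        n, k = 6, 3
        pmf = _ewens_conditional_pmf(n, k)
        f_probs = {}
        for part, p in pmf.items():
            f = sum((c / n) ** 2 for c in part)
            f_probs[round(f, 9)] = f_probs.get(round(f, 9), 0.0) + p
        rng = np.random.default_rng(4)
        theta = _ewens_theta_for_k(n, k)
        draws = {}
        got = 0
        while got < 4000:
            kk, f = _crp_sample_F(n, theta, rng)
            if kk == k:
                draws[round(f, 9)] = draws.get(round(f, 9), 0) + 1
                got += 1
        for f, p in f_probs.items():
            assert draws.get(f, 0) / got == pytest.approx(p, abs=0.03)


class TestMultilocusTajima:
    def test_null_self_consistency(self):
        """All observed D=0 against a symmetric-ish null: p near 0.5."""
        loci = [(10, 8, 8 / harmonic_a(9))] * 6
        res = multilocus_tajima(loci, reps=2000, seed=5)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert 0.35 < res.p_one_sided < 0.65

    def test_single_locus_reduction(self):
        bank = NullBank(7)
        loci = [(12, 5, 2.0)]
        res = multilocus_tajima(loci, reps=1000, bank=bank)
        d = tajima_d_value(5, 12, 2.0)
        null = bank.fixed_S(12, 5, 1000)["D"]
        expect_p = (np.sum(null <= d) + 1) / (len(null) + 1)
        assert res.statistic == pytest.approx(d)
        assert res.p_one_sided == pytest.approx(expect_p)

    def test_all_monomorphic_errors(self):
        with pytest.raises(ValueError):
            multilocus_tajima([(10, 0, 0.0)], reps=100)


class TestHKA:
    def test_symmetric_loci_zero_x2(self):
        res = hka_test(np.array([5, 5]), np.array([10., 10.]),
                       np.array([10, 10]))
        assert res.X2 == pytest.approx(0.0, abs=1e-8)
        assert res.theta[0] == pytest.approx(res.theta[1], rel=1e-6)

    def test_observed_equals_expected(self):
        # construct observations exactly on the model surface
        theta, T, n = 2.0, 3.0, 12
        a = harmonic_a(n - 1)
        S = np.array([theta * a, theta * a])
        D = np.array([theta * (T + 1), theta * (T + 1)])
        res = hka_test(S, D, np.array([n, n]))
        assert res.X2 == pytest.approx(0.0, abs=1e-8)
        assert res.T == pytest.approx(T, rel=0.01)

    def test_grid_search_oracle(self):
        """X^2 minimum equals an independent dense grid minimization."""
        rng = np.random.default_rng(6)
        L = 5
        n = rng.integers(8, 20, size=L)
        S = rng.integers(1, 25, size=L).astype(float)
        D = rng.integers(1, 40, size=L).astype(float)
        res = hka_test(S, D, n)
        a = np.array([harmonic_a(int(x) - 1) for x in n])
        b = np.array([harmonic_b(int(x) - 1) for x in n])

        def x2(T, thetas):
            es = thetas * a
            vs = es + thetas**2 * b
            ed = thetas * (T + 1)
            vd = ed + thetas**2
            return float(np.sum((S - es) ** 2 / vs + (D - ed) ** 2 / vd))

        best = np.inf
        for T in np.linspace(max(res.T - 1.0, 0.01), res.T + 1.0, 120):
            th = np.empty(L)
            for i in range(L):
                grid = np.linspace(0.05, 40, 3500)
                vals = ((S[i] - grid * a[i]) ** 2
                        / (grid * a[i] + grid**2 * b[i])
                        + (D[i] - grid * (T + 1)) ** 2
                        / (grid * (T + 1) + grid**2))
                th[i] = grid[int(np.argmin(vals))]
            best = min(best, x2(T, th))
        assert res.X2 <= best + 1e-4

    def test_uninformative_loci_dropped(self):
        res = hka_test(np.array([0, 5, 6]), np.array([0., 8., 9.]),
                       np.array([10, 10, 10]))
        assert res.dropped == [0]
        assert res.df == 1


class TestCompound:
    def test_all_null_components_not_rejected(self):
        bank = NullBank(9)
        tester = CompoundTester(bank, reps=1500, alpha=0.05,
                                conditioning="fixed_S")
        # a locus exactly at the null centre: D=0, H=0, F low
        res = tester.test_locus(d_obs=0.0, h_obs=0.0, f_obs=0.05,
                                n=20, S_obs=10)
        assert not res.reject_hew and not res.reject_dhew
        assert res.p_components["p_D"] > 0.05

    def test_extreme_locus_rejected(self):
        bank = NullBank(10)
        tester = CompoundTester(bank, reps=1500, alpha=0.05,
                                conditioning="fixed_S")
        res = tester.test_locus(d_obs=-3.5, h_obs=-5.0, f_obs=0.99,
                                n=20, S_obs=10)
        assert res.reject_hew and res.reject_dhew

    def test_calibrated_size_on_fresh_nulls(self):
        """Applying the calibrated threshold to fresh neutral draws gives a
        rejection rate near the nominal alpha (the point of calibration)."""
        from pinepop.neutrality import _empirical_p_vector

        bank = NullBank(11)
        tester = CompoundTester(bank, reps=2000, alpha=0.05,
                                conditioning="fixed_S")
        res = tester.test_locus(0.0, 0.0, 0.5, n=20, S_obs=8)
        a_dhew = res.p_components["alpha_prime_dhew"]
        assert 0.0 < a_dhew < 1.0
        fresh = sim_neutral_stats(20, 1500, S=8, seed=123)
        _, banks = tester._calibrate(20, 8, "DHEW")
        pD = _empirical_p_vector(banks["sD"], fresh["D"], "low")
        pH = _empirical_p_vector(banks["sH"], fresh["H"], "low")
        pF = _empirical_p_vector(banks["sF"], fresh["F"], "high")
        rate = np.mean((pD <= a_dhew) & (pH <= a_dhew) & (pF <= a_dhew))
        assert 0.02 <= rate <= 0.09


class TestFastSimulatorAgreement:
    @pytest.mark.parametrize("mode", ["theta", "S"])
    def test_fast_matches_reference(self, mode):
        from scipy.stats import ks_2samp

        kwargs = dict(theta=5.0) if mode == "theta" else dict(S=12)
        f = sim_neutral_stats(15, 2500, seed=21, fast=True, **kwargs)
        p = sim_neutral_stats(15, 700, seed=22, fast=False, **kwargs)
        for key in ("D", "H", "F", "S"):
            a = f[key][~np.isnan(f[key])]
            b = p[key][~np.isnan(p[key])]
            assert ks_2samp(a, b).pvalue > 0.005
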