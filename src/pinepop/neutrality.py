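"""Site-frequency-spectrum and haplotype neutrality tests with coalescent nulls.

Implemented tests
-----------------
* Tajima's D (per locus and multilocus mean, null by coalescent simulation).
* Fay & Wu's H, normalized following Zeng et al. (2006) (theta_pi - theta_L
  over its estimated standard deviation); requires outgroup polarization.
* Ewens-Watterson haplotype homozygosity F with the Ewens-sampling-formula
  null conditional on (n, k).
* Compound tests HEW (H & EW) and DHEW (D & H & EW): the component
  significance level alpha' is calibrated by bisection on jointly simulated
  nulls so the compound size equals the nominal alpha (Zeng et al. 2007).
* Multilocus HKA: polymorphism/divergence consistency across loci, X^2
  minimized over (T, theta_i), p from chi-square with (loci - 1) df.

One-sided directions are the selection-detection directions: D negative,
H negative, F high (homozygosity excess).  Permutation/simulation p-values
use the (b+1)/(B+1) estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

from .coalescent import simulate_genealogy
from .datamodel import HaplotypeSet, VariantTable
from .diversity import harmonic_a, harmonic_b

__all__ = [
    "tajima_constants",
    "tajima_d_value",
    "tajima_d",
    "multilocus_tajima",
    "fay_wu_h_value",
    "fay_wu_h",
    "ewens_watterson",
    "CompoundTester",
    "hka_test",
    "HKAResult",
    "NullBank",
    "sim_neutral_stats",
]


# --- statistic values from counts -------------------------------------------


def tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima (1989): Var(d) = e1*S + e2*S*(S-1)."""
    a1 = harmonic_a(n - 1)
    a2 = harmonic_b(n - 1)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    return c1 / a1, c2 / (a1 * a1 + a2)


def tajima_d_value(S: int, n: int, k_mean: float) -> float:
    """Tajima's D from S, n and the mean pairwise difference count k_mean
    (locus totals).  Undefined (nan) at S=0."""
    if S == 0:
        return float("nan")
    a1 = harmonic_a(n - 1)
    e1, e2 = tajima_constants(n)
    num = k_mean - S / a1
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        # n=3 is degenerate: every site has counts {1,2}, so num == 0 always
        return 0.0 if abs(num) < 1e-9 else float("nan")
    return num / math.sqrt(var)


def _k_mean_from_vt(vt: VariantTable) -> float:
    """Mean pairwise difference count (locus total, pairwise deletion,
    SNPs only)."""
    snp = vt.snp_only()
    total = 0.0
    for i in range(snp.S):
        geno = snp.genotypes[i]
        called = geno[geno >= 0]
        nc = len(called)
        if nc < 2:
            continue
        counts = np.bincount(called)
        pairs = nc * (nc - 1) / 2
        same = float(np.sum(counts * (counts - 1) / 2))
        total += (pairs - same) / pairs
    return total


def _xi_from_vt(vt: VariantTable) -> np.ndarray:
    """Derived counts of polarized biallelic SNP rows."""
    snp = vt.snp_only()
    xi = snp.sites["derived_count"].to_numpy()
    biallelic = np.array([len(a.split(",")) == 2 for a in snp.sites["alleles"]])
    return xi[(xi >= 1) & biallelic]


def fay_wu_h_value(xi: np.ndarray, n: int) -> tuple[float, float]:
    """(normalized H, unnormalized theta_pi - theta_H) from derived counts.

    theta_pi = sum 2 xi (n-xi) / (n(n-1)); theta_L = sum xi / (n-1);
    theta_H = sum 2 xi^2 / (n(n-1)); normalization per Zeng et al. (2006):
    H = (theta_pi - theta_L)/sqrt(Var), with theta and theta^2 estimated from
    S by Watterson moments.
    """
    xi = np.asarray(xi, float)
    xi = xi[(xi >= 1) & (xi <= n - 1)]
    S = len(xi)
    if S == 0:
        return float("nan"), float("nan")
    tp = float(np.sum(2.0 * xi * (n - xi)) / (n * (n - 1)))
    tl = float(np.sum(xi) / (n - 1))
    th = float(np.sum(2.0 * xi * xi) / (n * (n - 1)))
    an = harmonic_a(n - 1)
    bn = harmonic_b(n - 1)
    bn1 = harmonic_b(n)
    theta_w = S / an
    theta_sq = S * (S - 1) / (an * an + bn) if S > 1 else 0.0
    var = (n - 2) / (6.0 * (n - 1)) * theta_w + (
        18.0 * n * n * (3.0 * n + 2.0) * bn1
        - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1) ** 2) * theta_sq
    if var <= 0:
        return 0.0, tp - th
    return (tp - tl) / math.sqrt(var), tp - th


# --- joint neutral simulation of (D, H, F) ----------------------------------


def _haplotype_homozygosity(keys: list) -> float:
    counts: dict = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    n = len(keys)
    return sum(c * c for c in counts.values()) / (n * n)


def _tajima_d_vec(S: np.ndarray, n: int, tp: np.ndarray) -> np.ndarray:
    a1 = harmonic_a(n - 1)
    e1, e2 = tajima_constants(n)
    num = tp - S / a1
    var = e1 * S + e2 * S * (S - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / np.sqrt(var)
    d = np.where(var <= 0, np.where(np.abs(num) < 1e-9, 0.0, np.nan), d)
    return np.where(S == 0, np.nan, d)


def _fay_wu_h_vec(S: np.ndarray, n: int, tp: np.ndarray, tl: np.ndarray
                  ) -> np.ndarray:
    an = harmonic_a(n - 1)
    bn = harmonic_b(n - 1)
    bn1 = harmonic_b(n)
    theta_w = S / an
    theta_sq = np.where(S > 1, S * (S - 1) / (an * an + bn), 0.0)
    var = (n - 2) / (6.0 * (n - 1)) * theta_w + (
        18.0 * n * n * (3.0 * n + 2.0) * bn1
        - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1) ** 2) * theta_sq
    with np.errstate(invalid="ignore", divide="ignore"):
        h = (tp - tl) / np.sqrt(var)
    h = np.where(var <= 0, 0.0, h)
    return np.where(S == 0, np.nan, h)


def sim_neutral_stats(
    n: int,
    reps: int,
    theta: float | None = None,
    S: int | None = None,
    seed=None,
    fast: bool = True,
) -> dict[str, np.ndarray]:
    """Simulate joint (D, H_norm, F, S, k) under the neutral panmictic
    coalescent, fixed-theta (locus total) or fixed-S conditioning.

    Returns arrays of length ``reps``; D and H are nan for S=0 replicates
    (possible only in fixed-theta mode).  ``fast`` selects the compiled
    simulator; the pure-Python path below is the reference implementation
    (tests compare the two distributionally).
    """
    if (theta is None) == (S is None):
        raise ValueError("give exactly one of theta or S")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fast:
        from ._neutral_fast import neutral_reps

        arr = neutral_reps(n, reps, theta=theta, S=S,
                           seed=int(rng.integers(2**31 - 1)))
        Sv, tp, tl, F = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
        return {
            "D": _tajima_d_vec(Sv, n, tp),
            "H": _fay_wu_h_vec(Sv, n, tp, tl),
            "F": F,
            "S": Sv,
            "k": tp,
            "k_hap": arr[:, 4],
        }
    out = {k: np.empty(reps) for k in ("D", "H", "F", "S", "k", "k_hap")}
    for r in range(reps):
        g = simulate_genealogy(n, rng)
        bl = g.branch_lengths()
        total = bl.sum()
        nmut = int(rng.poisson(theta * total)) if theta is not None else int(S)
        if nmut == 0:
            out["D"][r] = out["H"][r] = float("nan")
            out["F"][r] = 1.0
            out["S"][r] = 0
            out["k"][r] = 0.0
            out["k_hap"][r] = 1
            continue
        branches = rng.choice(g.n_nodes, size=nmut, p=bl / total)
        masks = g.leaf_masks()
        xi = np.array([masks[int(b)].bit_count() for b in branches], float)
        keys = [0] * n
        for j, b in enumerate(branches):
            m = masks[int(b)]
            for leaf in range(n):
                if m >> leaf & 1:
                    keys[leaf] |= 1 << j
        tp = float(np.sum(2.0 * xi * (n - xi)) / (n * (n - 1)))
        out["D"][r] = tajima_d_value(nmut, n, tp)
        out["H"][r], _ = fay_wu_h_value(xi, n)
        out["F"][r] = _haplotype_homozygosity(keys)
        out["S"][r] = nmut
        out["k"][r] = tp
        out["k_hap"][r] = len(set(keys))
    return out


class NullBank:
    """Cache of joint neutral null simulations keyed by conditioning.

    Seeds are derived deterministically from the master seed and the key so
    re-running an analysis reproduces every bank.
    """

    def __init__(self, master_seed: int | None = None):
        self.master_seed = 0 if master_seed is None else int(master_seed)
        self._cache: dict = {}

    def fixed_S(self, n: int, S: int, reps: int) -> dict[str, np.ndarray]:
        key = ("S", n, S, reps)
        if key not in self._cache:
            rng = np.random.default_rng([self.master_seed, 1, n, S, reps])
            self._cache[key] = sim_neutral_stats(n, reps, S=S, seed=rng)
        return self._cache[key]

    def fixed_theta(self, n: int, theta: float, reps: int) -> dict[str, np.ndarray]:
        key = ("theta", n, round(theta, 10), reps)
        if key not in self._cache:
            rng = np.random.default_rng(
                [self.master_seed, 2, n, hash(round(theta, 10)) % 2**31, reps]
            )
            self._cache[key] = sim_neutral_stats(n, reps, theta=theta, seed=rng)
        return self._cache[key]


def _p_low(null_vals: np.ndarray, obs: float) -> float:
    """One-sided lower-tail p with the (b+1)/(B+1) estimator (nan-safe)."""
    v = null_vals[~np.isnan(null_vals)]
    if len(v) == 0:
        return float("nan")
    return (np.sum(v <= obs) + 1.0) / (len(v) + 1.0)


def _p_high(null_vals: np.ndarray, obs: float) -> float:
    v = null_vals[~np.isnan(null_vals)]
    if len(v) == 0:
        return float("nan")
    return (np.sum(v >= obs) + 1.0) / (len(v) + 1.0)


# --- per-locus tests ---------------------------------------------------------


@dataclass
class TestResult:
    statistic: float
    p_one_sided: float
    p_two_sided: float | None = None
    extra: dict = field(default_factory=dict)


def tajima_d(
    vt: VariantTable,
    reps: int = 1000,
    bank: NullBank | None = None,
    seed: int | None = None,
) -> TestResult:
    """Tajima's D for one locus with a fixed-S coalescent p-value.

    One-sided p is the lower tail (singleton excess); the two-sided value
    doubles the smaller tail.
    """
    n = vt.n_samples
    S = vt.S_snp
    d = tajima_d_value(S, n, _k_mean_from_vt(vt))
    if S == 0:
        return TestResult(float("nan"), float("nan"))
    bank = bank or NullBank(seed)
    null = bank.fixed_S(n, S, reps)["D"]
    p_lo = _p_low(null, d)
    p_hi = _p_high(null, d)
    return TestResult(d, p_lo, min(1.0, 2.0 * min(p_lo, p_hi)))


def multilocus_tajima(
    loci: list[tuple[int, int, float]],
    reps: int = 1000,
    bank: NullBank | None = None,
    seed: int | None = None,
) -> TestResult:
    """Multilocus mean Tajima's D with a coalescent null.

    ``loci`` holds (n, S, k_mean) per locus; S=0 loci are excluded.  The null
    distribution is the mean over loci of independently simulated fixed-S D
    values; p is one-sided for a negative mean.
    """
    usable = [(n, S, k) for n, S, k in loci if S > 0]
    if not usable:
        raise ValueError("no locus with S > 0")
    obs = float(np.mean([tajima_d_value(S, n, k) for n, S, k in usable]))
    bank = bank or NullBank(seed)
    per_locus = [bank.fixed_S(n, S, reps)["D"] for n, S, _ in usable]
    null_mean = np.mean(np.vstack(per_locus), axis=0)
    p_lo = _p_low(null_mean, obs)
    p_hi = _p_high(null_mean, obs)
    return TestResult(obs, p_lo, min(1.0, 2.0 * min(p_lo, p_hi)),
                      extra={"n_loci": len(usable)})


def fay_wu_h(
    vt: VariantTable,
    reps: int = 1000,
    bank: NullBank | None = None,
    seed: int | None = None,
) -> TestResult:
    """Normalized Fay & Wu H with a fixed-S coalescent p-value (lower tail:
    excess of high-frequency derived alleles).  Sites with unknown ancestral
    state are excluded; nan when nothing is polarizable."""
    n = vt.n_samples
    xi = _xi_from_vt(vt)
    h, h_unnorm = fay_wu_h_value(xi, n)
    if math.isnan(h):
        return TestResult(float("nan"), float("nan"))
    S = len(xi)
    bank = bank or NullBank(seed)
    null = bank.fixed_S(n, S, reps)["H"]
    return TestResult(h, _p_low(null, h), extra={"unnormalized": h_unnorm, "S_polarized": S})


# --- Ewens-Watterson ---------------------------------------------------------


def _ewens_theta_for_k(n: int, k: int) -> float:
    """theta solving E[K | theta, n] = sum theta/(theta+i) for i=0..n-1 = k."""
    if k <= 1:
        return 1e-9
    if k >= n:
        return 1e9

    def ek(theta: float) -> float:
        i = np.arange(n, dtype=float)
        return float(np.sum(theta / (theta + i))) - k

    return brentq(ek, 1e-9, 1e9, xtol=1e-12, rtol=1e-12)


def _crp_sample_F(n: int, theta: float, rng: np.random.Generator) -> tuple[int, float]:
    """One Ewens partition by the Chinese-restaurant construction;
    returns (k, F = sum p_i^2)."""
    counts: list[int] = []
    for i in range(n):
        if rng.random() * (theta + i) < theta:
            counts.append(1)
        else:
            r = rng.random() * i
            acc = 0.0
            for j, c in enumerate(counts):
                acc += c
                if r < acc:
                    counts[j] += 1
                    break
        # note: first customer always opens a table (i=0 branch)
    arr = np.array(counts, float) / n
    return len(counts), float(np.sum(arr * arr))


def ewens_watterson(
    hs_or_counts,
    reps: int = 1000,
    seed=None,
    max_draws_factor: int = 50,
) -> TestResult:
    """Ewens-Watterson homozygosity test.

    F = sum p_i^2 of the observed haplotype configuration; the null is the
    Ewens sampling formula conditional on (n, k): partitions are drawn by the
    Chinese-restaurant process at the theta solving E[K]=k and rejected
    unless K=k (the conditional law is theta-free, so rejection sampling is
    exact).  One-sided p = Pr(F_null >= F_obs) — homozygosity excess.
    """
    if isinstance(hs_or_counts, HaplotypeSet):
        n = hs_or_counts.n
        k = hs_or_counts.N
        f_obs = hs_or_counts.homozygosity
    else:
        counts = np.asarray(hs_or_counts, float)
        n = int(counts.sum())
        k = len(counts)
        p = counts / n
        f_obs = float(np.sum(p * p))
    if n < 2:
        raise ValueError("EW test needs n >= 2")
    flags = {}
    if k == 1 or k == n:
        flags["degenerate"] = True
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = _ewens_theta_for_k(n, k)
    fs = []
    draws = 0
    limit = reps * max_draws_factor
    while len(fs) < reps and draws < limit:
        draws += 1
        kk, f = _crp_sample_F(n, theta, rng)
        if kk == k:
            fs.append(f)
    if not fs:
        # k=1 or k=n are deterministic partitions
        fs = [f_obs]
    fs = np.array(fs)
    p = _p_high(fs, f_obs)
    return TestResult(f_obs, p, extra={"k": k, "n": n, "null_draws": len(fs), **flags})


# --- compound tests ----------------------------------------------------------


def _empirical_p_vector(null_sorted: np.ndarray, values: np.ndarray, tail: str) -> np.ndarray:
    """Vectorized (b+1)/(B+1) one-sided p of ``values`` against a sorted null."""
    B = len(null_sorted)
    if tail == "low":
        cnt = np.searchsorted(null_sorted, values, side="right")
    else:
        cnt = B - np.searchsorted(null_sorted, values, side="left")
    return (cnt + 1.0) / (B + 1.0)


@dataclass
class CompoundResult:
    alpha_prime: float
    reject_hew: bool
    reject_dhew: bool
    p_components: dict[str, float]
    usable_reps: int


class CompoundTester:
    """HEW / DHEW compound neutrality tests with simulation calibration.

    For each conditioning (n plus fixed-theta at the locus's Watterson
    estimate, or fixed-S), the joint null of (D, H, F) is simulated once.
    Component p-values of each null replicate against the bank give the
    empirical joint law of the component p's; alpha' is the largest component
    threshold whose compound rejection rate does not exceed alpha (found on
    the sorted per-replicate max-p values, the bisection limit).  A locus
    rejects when all its component p's are <= alpha'.
    """

    def __init__(self, bank: NullBank, reps: int = 10000, alpha: float = 0.05,
                 conditioning: str = "fixed_theta"):
        if conditioning not in ("fixed_theta", "fixed_S"):
            raise ValueError("conditioning must be fixed_theta or fixed_S")
        self.bank = bank
        self.reps = reps
        self.alpha = alpha
        self.conditioning = conditioning
        self._cal_cache: dict = {}

    def _bank_for(self, n: int, S_obs: int) -> dict[str, np.ndarray]:
        if self.conditioning == "fixed_S":
            return self.bank.fixed_S(n, S_obs, self.reps)
        theta = S_obs / harmonic_a(n - 1)
        return self.bank.fixed_theta(n, theta, self.reps)

    def _calibrate(self, n: int, S_obs: int, which: str) -> tuple[float, dict]:
        key = (n, S_obs, which)
        if key in self._cal_cache:
            return self._cal_cache[key]
        null = self._bank_for(n, S_obs)
        ok = ~np.isnan(null["D"]) & ~np.isnan(null["H"])
        usable = int(ok.sum())
        if usable < self.reps / 10:
            raise ValueError(
                "too few usable fixed-theta replicates (S=0 draws dominate); "
                "use fixed_S conditioning"
            )
        D, H, F = null["D"][ok], null["H"][ok], null["F"][ok]
        sD, sH, sF = np.sort(D), np.sort(H), np.sort(F)
        pD = _empirical_p_vector(sD, D, "low")
        pH = _empirical_p_vector(sH, H, "low")
        pF = _empirical_p_vector(sF, F, "high")
        if which == "HEW":
            joint_max = np.maximum(pH, pF)
        else:
            joint_max = np.maximum.reduce([pD, pH, pF])
        # compound rejects iff max component p <= alpha'; choose alpha' as the
        # alpha-quantile of the max-p distribution (largest threshold with
        # size <= alpha).
        js = np.sort(joint_max)
        m = len(js)
        idx = int(math.floor(self.alpha * m)) - 1
        alpha_prime = float(js[idx]) if idx >= 0 else 0.0
        banks = {"sD": sD, "sH": sH, "sF": sF, "usable": usable}
        self._cal_cache[key] = (alpha_prime, banks)
        return self._cal_cache[key]

    def test_locus(self, d_obs: float, h_obs: float, f_obs: float,
                   n: int, S_obs: int) -> CompoundResult:
        if S_obs <= 0:
            raise ValueError("compound tests need S >= 1")
        a_hew, banks = self._calibrate(n, S_obs, "HEW")
        a_dhew, _ = self._calibrate(n, S_obs, "DHEW")
        pD = float(_empirical_p_vector(banks["sD"], np.array([d_obs]), "low")[0])
        pH = float(_empirical_p_vector(banks["sH"], np.array([h_obs]), "low")[0])
        pF = float(_empirical_p_vector(banks["sF"], np.array([f_obs]), "high")[0])
        hew = pH <= a_hew and pF <= a_hew
        dhew = pD <= a_dhew and pH <= a_dhew and pF <= a_dhew
        return CompoundResult(
            a_dhew, hew, dhew,
            {"p_D": pD, "p_H": pH, "p_EW": pF,
             "alpha_prime_hew": a_hew, "alpha_prime_dhew": a_dhew},
            banks["usable"],
        )


# --- HKA ---------------------------------------------------------------------


@dataclass
class HKAResult:
    X2: float
    p_value: float
    df: int
    T: float
    theta: np.ndarray
    expected_S: np.ndarray
    expected_D: np.ndarray
    dropped: list[int]


def _hka_x2_at_T(T: float, S, D, a, b) -> tuple[float, np.ndarray]:
    """Profile X^2 over per-locus theta at divergence time T."""
    thetas = np.empty(len(S))
    x2 = 0.0
    for i in range(len(S)):
        ai, bi, si, di = a[i], b[i], S[i], D[i]

        def contrib(th: float) -> float:
            es = th * ai
            vs = es + th * th * bi
            ed = th * (T + 1.0)
            vd = ed + th * th
            return (si - es) ** 2 / vs + (di - ed) ** 2 / vd

        start = max((si + di) / (ai + T + 1.0), 1e-6)
        res = minimize_scalar(
            lambda x: contrib(math.exp(x)),
            bounds=(math.log(start) - 6, math.log(start) + 6),
            method="bounded",
            options={"xatol": 1e-12},
        )
        thetas[i] = math.exp(res.x)
        x2 += res.fun
    return x2, thetas


def hka_test(
    S: np.ndarray,
    D: np.ndarray,
    n: np.ndarray,
) -> HKAResult:
    """Multilocus HKA test (one population + one outgroup sequence per locus).

    Under neutrality E[S_i] = theta_i * a_{n_i-1} with
    Var = E[S_i] + theta_i^2 * b_{n_i-1}, and E[D_i] = theta_i * (T+1) with
    Var = E[D_i] + theta_i^2 (T in 2N generations; the +1 is the coalescent
    contribution of the sampled lineage).  (T, theta_i) minimize
    X^2 = sum_i (S_i-E)^2/Var_S + (D_i-E)^2/Var_D; p from chi2 with df = L-1.
    Loci with S=0 and D=0 carry no information and are dropped.
    """
    S = np.asarray(S, float)
    D = np.asarray(D, float)
    n = np.asarray(n, int)
    keep = ~((S == 0) & (D == 0))
    dropped = list(np.where(~keep)[0])
    S, D, n = S[keep], D[keep], n[keep]
    if len(S) < 2:
        raise ValueError("HKA needs >= 2 informative loci")
    a = np.array([harmonic_a(int(ni) - 1) for ni in n])
    b = np.array([harmonic_b(int(ni) - 1) for ni in n])
    # moment start for T: sum D = (T+1) sum theta, theta_i = (S+D)/(a+T+1)
    def moment_gap(T: float) -> float:
        th = (S + D) / (a + T + 1.0)
        return float(np.sum(D) - (T + 1.0) * np.sum(th))

    try:
        T0 = brentq(moment_gap, 1e-6, 1e6)
    except ValueError:
        T0 = max(float(np.sum(D)) / max(float(np.sum(S)), 1.0), 0.1)
    res = minimize_scalar(
        lambda lt: _hka_x2_at_T(math.exp(lt), S, D, a, b)[0],
        bounds=(math.log(max(T0, 1e-4)) - 4, math.log(max(T0, 1e-4)) + 4),
        method="bounded",
        options={"xatol": 1e-10},
    )
    T = math.exp(res.x)
    x2, thetas = _hka_x2_at_T(T, S, D, a, b)
    df = len(S) - 1
    p = float(chi2.sf(x2, df))
    return HKAResult(float(x2), p, df, float(T), thetas,
                     thetas * a, thetas * (T + 1.0), dropped)
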