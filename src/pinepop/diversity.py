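"""Within-group diversity statistics.

Per-locus quantities: nucleotide diversity pi (per site, pairwise deletion),
Watterson's theta_W = S / (a_{n-1} L), haplotype number and diversity H_d,
singleton counts, and silent-site lengths (noncoding columns plus the
Nei-Gojobori synonymous-site fraction of coding columns).

The multilocus theta estimate is Bayesian: a single per-site theta shared
across loci, likelihood = product over loci of the closed-form neutral
coalescent distribution of the segregating-site count S given (theta*L, n),
sampled by Metropolis on log10(theta) with a uniform prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import HaplotypeSet, LocusAlignment, SiteAnnotation, VariantTable

__all__ = [
    "harmonic_a",
    "nucleotide_diversity",
    "watterson_theta",
    "haplotype_diversity",
    "singleton_count",
    "site_class_lengths",
    "segsite_log_pmf",
    "multilocus_theta_posterior",
    "ThetaPosterior",
]


def harmonic_a(m: int) -> float:
    """a_m = sum_{i=1}^{m} 1/i (Watterson's denominator uses a_{n-1})."""
    return float(sum(1.0 / i for i in range(1, m + 1)))


def harmonic_b(m: int) -> float:
    """b_m = sum_{i=1}^{m} 1/i^2."""
    return float(sum(1.0 / (i * i) for i in range(1, m + 1)))


def nucleotide_diversity(
    vt: VariantTable,
    L_effective: int | float,
    site_mask: np.ndarray | None = None,
) -> float:
    """pi per site: mean pairwise difference count over called pairs / L.

    SNP rows only (indels excluded from per-site statistics).  Pairwise
    deletion: each site contributes (differing called pairs)/(called pairs).
    ``site_mask`` (length L_total, boolean) optionally restricts to a site
    class, e.g. silent columns.
    """
    if vt.n_samples < 2:
        raise ValueError("pi requires >= 2 samples")
    if L_effective <= 0:
        raise ValueError("L_effective must be positive")
    snp = vt.snp_only()
    total = 0.0
    for i, row in enumerate(snp.sites.itertuples(index=False)):
        if site_mask is not None and not site_mask[row.position]:
            continue
        geno = snp.genotypes[i]
        called = geno[geno >= 0]
        nc = len(called)
        if nc < 2:
            continue
        counts = np.bincount(called)
        pairs = nc * (nc - 1) / 2
        same = float(np.sum(counts * (counts - 1) / 2))
        total += (pairs - same) / pairs
    return total / L_effective


def watterson_theta(S: int, n: int, L: int | float) -> float:
    """theta_W per site = S / (a_{n-1} L)."""
    if n < 2:
        raise ValueError("theta_W requires n >= 2")
    if L <= 0:
        raise ValueError("L must be positive")
    if S == 0:
        return 0.0
    return S / (harmonic_a(n - 1) * L)


def haplotype_diversity(hs: HaplotypeSet) -> tuple[float, float]:
    """Nei's haplotype diversity H_d = n/(n-1) (1 - sum p_i^2) and its SD.

    SD from Nei (1987) eq. 8.12:
    V = 2/(n(n-1)) * [2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2].
    """
    n = hs.n
    if n < 2:
        raise ValueError("H_d requires n >= 2")
    p = hs.frequencies
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2 * s2) + s2 - s2 * s2)
    return hd, math.sqrt(max(var, 0.0))


def singleton_count(vt: VariantTable) -> int:
    """S_g: sites whose minor allele is carried by exactly one sample."""
    return vt.S_singleton


# --- silent sites (Nei-Gojobori counting on group consensus codons) ---------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def synonymous_fraction(codon: str) -> float:
    """Nei-Gojobori synonymous-site count of one codon (0..3).

    Each position contributes (number of the 3 single-base changes that are
    synonymous)/3; changes to or from stop codons count as nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _CODON_TABLE[alt] == aa:
                syn += 1
        total += syn / 3.0
    return total


def consensus_sequence(aln: LocusAlignment, subset=None) -> str:
    """Majority base per column (ties broken alphabetically); N where no base."""
    mat = aln.rows(subset)
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        bases = [c for c in col if c in "ACGT"]
        if not bases:
            out.append("N")
            continue
        uniq, counts = np.unique(bases, return_counts=True)
        out.append(str(uniq[np.argmax(counts)]))
    return "".join(out)


def site_class_lengths(
    aln: LocusAlignment,
    annot: SiteAnnotation | None,
    subset=None,
) -> tuple[int, float | None]:
    """(L_total, L_silent) for a locus.

    L_silent = noncoding columns + synonymous-site fraction of coding codons,
    the latter by Nei-Gojobori counting on the group consensus.  Codons
    containing N, gaps or coding for stop are skipped (contribute 0 sites of
    either class).  Returns L_silent=None when no annotation is available.
    """
    L = aln.length
    if annot is None:
        return L, None
    coding = annot.site_class(L)
    cons = consensus_sequence(aln, subset)
    silent = float(np.sum(~coding))
    for start, end, frame in annot.coding_intervals:
        if (end - start - frame) < 0:
            raise ValueError(f"{aln.locus_id}: frame {frame} incompatible with interval")
        for cstart in range(start + frame, end - 2, 3):
            codon = cons[cstart:cstart + 3]
            if any(c not in "ACGT" for c in codon):
                continue
            if _CODON_TABLE[codon] == "*":
                continue
            silent += synonymous_fraction(codon)
    return L, silent


# --- multilocus theta posterior ---------------------------------------------


def segsite_log_pmf(s: int, theta_locus: float, n: int) -> float:
    """log P(S = s) under the neutral coalescent with locus-total theta.

    Closed form (Tavare 1984):
    P(S=s) = sum_{i=1}^{n-1} (-1)^{i+1} C(n-1,i) * i/(i+theta) * (theta/(i+theta))^s.
    Summed with math.fsum; accurate for moderate n (guarded at n <= 60 by the
    caller, which switches to a Monte-Carlo likelihood beyond that).
    """
    if theta_locus <= 0:
        return 0.0 if s == 0 else -np.inf
    terms = []
    for i in range(1, n):
        c = math.comb(n - 1, i)
        val = c * (i / (i + theta_locus)) * (theta_locus / (i + theta_locus)) ** s
        terms.append(val if i % 2 == 1 else -val)
    p = math.fsum(terms)
    if p <= 0:
        return -np.inf
    return math.log(p)


def _segsite_loglik_grid(
    S: np.ndarray, n: np.ndarray, L: np.ndarray, thetas: np.ndarray,
    mc_draws: int = 4000, rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Total log-likelihood over loci for each per-site theta in ``thetas``.

    Uses the closed form for n <= 60 and S <= 500 (vectorized over the theta
    grid) and a Monte-Carlo likelihood elsewhere: one common set of
    coalescent tree-length draws per sample size, S | length ~ Poisson.
    """
    from scipy.special import gammaln as _gl

    out = np.zeros(len(thetas))
    rng = rng or np.random.default_rng(0)
    tree_lengths: dict[int, np.ndarray] = {}
    for li in range(len(S)):
        nl, s, tl = int(n[li]), int(S[li]), thetas * L[li]
        if nl <= 60 and s <= 500:
            i = np.arange(1, nl, dtype=float)
            logC = _gl(nl) - _gl(i + 1) - _gl(nl - i)
            t = tl[:, None]
            logterm = (logC[None, :] + np.log(i / (i + t))
                       + s * np.log(t / (i + t)))
            sign = np.where(np.arange(1, nl) % 2 == 1, 1.0, -1.0)
            m = logterm.max(axis=1, keepdims=True)
            p = np.sum(sign[None, :] * np.exp(logterm - m), axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                lp = np.where(p > 0, np.log(np.maximum(p, 1e-300)) + m[:, 0],
                              -np.inf)
        else:
            if nl not in tree_lengths:
                k = np.arange(2, nl + 1)
                w = rng.exponential(1.0 / (k * (k - 1)), size=(mc_draws, nl - 1))
                tree_lengths[nl] = (w * k).sum(axis=1)  # total length, 4N units
            lam = tl[:, None] * tree_lengths[nl][None, :]
            logp = s * np.log(lam) - lam - _gl(s + 1)
            m = logp.max(axis=1, keepdims=True)
            lp = m[:, 0] + np.log(np.mean(np.exp(logp - m), axis=1))
        out += lp
    return out


@dataclass
class ThetaPosterior:
    median: float
    ci_low: float
    ci_high: float
    samples: np.ndarray
    acceptance_rate: float
    ess: float
    warnings: list[str]


def _ess(x: np.ndarray) -> float:
    """Effective sample size by initial-positive-sequence autocorrelation sum."""
    x = np.asarray(x, float)
    m = len(x)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return float(m)
    rho_sum = 0.0
    for lag in range(1, min(m - 1, 1000)):
        rho = float(np.dot(x[:-lag], x[lag:])) / denom
        if rho <= 0.0:
            break
        rho_sum += rho
    return m / (1.0 + 2.0 * rho_sum)


def multilocus_theta_posterior(
    S: np.ndarray,
    n: np.ndarray,
    L: np.ndarray,
    burn_in: int = 5000,
    samples: int = 100_000,
    log10_prior: tuple[float, float] = (-5.0, -1.0),
    proposal_sd: float = 0.15,
    seed: int | None = None,
) -> ThetaPosterior:
    """Posterior of a single per-site theta shared across loci.

    Metropolis on x = log10(theta) with uniform prior on ``log10_prior``;
    reports the posterior median, the central 95% credible interval, the
    acceptance rate and an autocorrelation-based effective sample size
    (a warning is recorded when ESS < 200).
    """
    S = np.asarray(S, int)
    n = np.asarray(n, int)
    L = np.asarray(L, float)
    if len(S) == 0:
        raise ValueError("need at least one locus")
    if np.any(n < 2):
        raise ValueError("all loci need n >= 2")
    rng = np.random.default_rng(seed)

    # cache log-likelihood on a fine grid; Metropolis interpolates linearly.
    # The grid is fine enough (2000 points over 4 decades) that interpolation
    # error is far below MC noise.
    lo, hi = log10_prior
    grid = np.linspace(lo, hi, 2001)
    loglik = _segsite_loglik_grid(S, n, L, 10.0**grid, rng=rng)

    def ll(x: float) -> float:
        return float(np.interp(x, grid, loglik))

    x = grid[np.argmax(loglik)]  # start at grid MLE
    cur = ll(x)
    chain = np.empty(samples)
    accepted = 0
    total = burn_in + samples
    prop = rng.normal(0.0, proposal_sd, size=total)
    unif = rng.random(total)
    for it in range(total):
        xn = x + prop[it]
        if lo <= xn <= hi:
            new = ll(xn)
            if new >= cur or unif[it] < math.exp(new - cur):
                x, cur = xn, new
                accepted += 1
        if it >= burn_in:
            chain[it - burn_in] = x
    thetas = 10.0**chain
    med = float(np.median(thetas))
    lo_ci, hi_ci = np.percentile(thetas, [2.5, 97.5])
    ess = _ess(chain)
    warns = []
    if ess < 200:
        warns.append(f"low effective sample size: {ess:.0f}")
    mle = grid[np.argmax(loglik)]
    if mle <= lo + 0.05 or mle >= hi - 0.05:
        warns.append("posterior mode at prior boundary")
    return ThetaPosterior(
        med, float(lo_ci), float(hi_ci), thetas,
        accepted / total, ess, warns,
    )
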