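"""Linkage disequilibrium and the population recombination rate.

Pairwise r^2 between biallelic informative sites within a locus, Fisher-exact
LD pruning, and the non-linear least-squares fit of the LD decay curve
E[r^2 | C = rho*d, n] (Hill & Weir 1988, with the sample-size adjustment)
that yields rho = 4*N_e*c per bp and the rho/theta ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import fisher_exact

from .datamodel import VariantTable

__all__ = ["LDPair", "RecombFit", "pairwise_r2", "ld_prune", "hill_weir_r2", "fit_rho"]


@dataclass(frozen=True)
class LDPair:
    locus_id: str
    pos_i: int
    pos_j: int
    distance: int
    r2: float
    fisher_p: float
    maf_i: float = 0.0
    maf_j: float = 0.0


@dataclass
class RecombFit:
    rho_per_bp: float
    se: float
    n_pairs: int
    rss: float
    at_boundary: bool
    rho_over_theta: float | None = None


def _informative_biallelic(vt: VariantTable) -> tuple[list[int], np.ndarray]:
    """Indices (into vt rows) of biallelic informative SNPs and genotypes."""
    idx = []
    for i, row in enumerate(vt.sites.itertuples(index=False)):
        if row.type != "SNP":
            continue
        if not row.is_informative:
            continue
        if len(row.alleles.split(",")) != 2:
            continue
        idx.append(i)
    return idx, vt.genotypes


def pairwise_r2(vt: VariantTable) -> list[LDPair]:
    """All within-locus pairs of biallelic informative sites.

    r^2 = (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B)) over pairwise-complete
    haploid samples; Fisher's exact p on the 2x2 haplotype count table.
    """
    idx, geno = _informative_biallelic(vt)
    if len(idx) < 2:
        return []
    pos = vt.sites["position"].to_numpy()
    maf = vt.sites["maf"].to_numpy()
    pairs = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            gi, gj = geno[i], geno[j]
            ok = (gi >= 0) & (gj >= 0)
            if ok.sum() < 2:
                continue
            x, y = gi[ok].astype(float), gj[ok].astype(float)
            pa, pb = x.mean(), y.mean()
            if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                continue
            pab = float(np.mean(x * y))
            r2 = (pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))
            table = np.array(
                [
                    [np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
                    [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))],
                ]
            )
            _, p = fisher_exact(table)
            pairs.append(
                LDPair(
                    vt.locus_id, int(pos[i]), int(pos[j]),
                    int(pos[j] - pos[i]), float(r2), float(p),
                    float(maf[i]), float(maf[j]),
                )
            )
    return pairs


def ld_prune(pairs: list[LDPair], alpha: float = 0.05) -> set[int]:
    """Greedy pruning of linked sites with Bonferroni-corrected Fisher tests.

    Returns the retained site positions.  While any pair is significant at
    alpha/m (m = number of tested pairs), the member with more significant
    partners is dropped; ties drop the lower-MAF site.
    """
    sites = sorted({p for pr in pairs for p in (pr.pos_i, pr.pos_j)})
    if not pairs:
        return set(sites)
    m = len(pairs)
    thresh = alpha / m
    maf = {}
    for pr in pairs:
        maf[pr.pos_i] = pr.maf_i
        maf[pr.pos_j] = pr.maf_j
    active = set(sites)
    sig = [(pr.pos_i, pr.pos_j) for pr in pairs if pr.fisher_p <= thresh]
    while True:
        live = [(a, b) for a, b in sig if a in active and b in active]
        if not live:
            return active
        degree: dict[int, int] = {}
        for a, b in live:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        # drop: max degree; tie -> lower MAF; tie -> higher position (stable)
        drop = max(degree, key=lambda s: (degree[s], -maf[s], s))
        active.discard(drop)


def hill_weir_r2(C: float | np.ndarray, n: int) -> float | np.ndarray:
    """Hill-Weir (1988) expectation of r^2 at scaled distance C = rho*d,
    with the 1/n sample-size adjustment."""
    C = np.asarray(C, float)
    t1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    t2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C * C)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    out = t1 * t2
    return float(out) if out.ndim == 0 else out


def _fit_rho_ls(d: np.ndarray, r2: np.ndarray, n: int) -> tuple[float, float]:
    """1-D least squares for rho >= 0; returns (rho, rss)."""

    def rss(log10_rho: float) -> float:
        rho = 10.0**log10_rho
        return float(np.sum((r2 - hill_weir_r2(rho * d, n)) ** 2))

    rss0 = float(np.sum((r2 - hill_weir_r2(np.zeros_like(d), n)) ** 2))
    grid = np.linspace(-8, 1, 181)
    vals = [rss(x) for x in grid]
    best = int(np.argmin(vals))
    if vals[best] >= rss0:
        return 0.0, rss0
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(rss, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    if res.fun >= rss0:
        return 0.0, rss0
    return float(10.0**res.x), float(res.fun)


def fit_rho(
    pairs: list[LDPair],
    n: int,
    theta_per_site: float | None = None,
    bootstrap_reps: int = 1000,
    seed=None,
) -> RecombFit:
    """Fit rho per bp from the r^2-vs-distance cloud.

    Least squares of observed r^2 against the Hill-Weir expectation at
    C = rho*d; rho constrained >= 0 (a boundary fit is flagged as absence of
    a recombination signal).  The SE is a bootstrap over loci; rho/theta uses
    the supplied Watterson theta per site of the same sample.
    """
    if len(pairs) < 10:
        raise ValueError("need >= 10 site pairs for a stable fit")
    d = np.array([p.distance for p in pairs], float)
    r2 = np.array([p.r2 for p in pairs], float)
    rho, rss = _fit_rho_ls(d, r2, n)
    loci = sorted({p.locus_id for p in pairs})
    rng = np.random.default_rng(seed)
    by_locus = {l: [i for i, p in enumerate(pairs) if p.locus_id == l] for l in loci}
    boots = []
    for _ in range(bootstrap_reps):
        pick = rng.choice(len(loci), size=len(loci), replace=True)
        idx = np.concatenate([by_locus[loci[i]] for i in pick])
        if len(idx) < 10:
            continue
        b, _ = _fit_rho_ls(d[idx], r2[idx], n)
        boots.append(b)
    se = float(np.std(boots)) if boots else float("nan")
    ratio = rho / theta_per_site if theta_per_site else None
    return RecombFit(rho, se, len(pairs), rss, at_boundary=(rho == 0.0),
                     rho_over_theta=ratio)
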