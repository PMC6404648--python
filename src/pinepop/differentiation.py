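"""Permutation-based differentiation and structure summaries.

AMOVA variance components and Phi-statistics (Excoffier et al. 1992) on
pairwise-difference distance matrices, pairwise Phi_ST-type F_ST, per-SNP
variance-partition F_ST, Hudson's (2000) nearest-neighbour statistic S_nn,
classic PCoA (Gower double-centering), and the minimum spanning network of
haplotypes (MST plus all co-minimal alternative edges).

Permutation p-values use the (b+1)/(B+1) estimator so a p of exactly zero is
never reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "pairwise_difference_matrix",
    "AmovaResult",
    "amova",
    "pairwise_fst",
    "per_site_fst",
    "snn_statistic",
    "snn",
    "SnnResult",
    "pcoa",
    "PcoaResult",
    "haplotype_msn",
]


def pairwise_difference_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise difference counts between character rows (N = missing,
    pairwise deletion)."""
    n = mat.shape[0]
    codes = np.full(mat.shape, -1, dtype=np.int8)
    for code, b in enumerate("ACGT-01"):
        codes[mat == b] = code
    D = np.zeros((n, n))
    for i in range(n):
        a = codes[i]
        sub = codes[i + 1:]
        diff = ((a != sub) & (a >= 0) & (sub >= 0)).sum(axis=1)
        D[i, i + 1:] = diff
        D[i + 1:, i] = diff
    return D


# --- AMOVA -------------------------------------------------------------------


@dataclass
class AmovaResult:
    components: dict[str, float]
    percentages: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float]
    df: dict[str, int]
    permutations: int


def _ssd(D2: np.ndarray, idx: list[np.ndarray]) -> float:
    """Sum over index blocks of (sum of squared distances)/(2 * block size)."""
    tot = 0.0
    for ii in idx:
        if len(ii) == 0:
            continue
        sub = D2[np.ix_(ii, ii)]
        tot += sub.sum() / (2.0 * len(ii))
    return tot


def _amova_components(
    D2: np.ndarray,
    pops: np.ndarray,
    groups: np.ndarray | None,
) -> tuple[dict[str, float], dict[str, int], dict[str, float]]:
    """Variance components of a 2- or 3-level AMOVA from squared distances."""
    N = len(pops)
    pop_ids = np.unique(pops)
    P = len(pop_ids)
    pop_idx = [np.where(pops == p)[0] for p in pop_ids]
    pop_sizes = np.array([len(ix) for ix in pop_idx], float)
    ssd_total = _ssd(D2, [np.arange(N)])
    ssd_wp = _ssd(D2, pop_idx)
    df_wp = N - P
    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    sigma_w = ms_wp

    if groups is None:
        ssd_ap = ssd_total - ssd_wp
        df_ap = P - 1
        ms_ap = ssd_ap / df_ap
        n_prime = (N - float(np.sum(pop_sizes**2)) / N) / (P - 1)
        sigma_a = (ms_ap - sigma_w) / n_prime
        comps = {"among_pops": sigma_a, "within_pops": sigma_w}
        df = {"among_pops": df_ap, "within_pops": df_wp}
        total = sigma_a + sigma_w
        phi = {"phi_st": sigma_a / total if total > 0 else 0.0}
        return comps, df, phi

    grp_ids = np.unique(groups)
    G = len(grp_ids)
    grp_idx = [np.where(groups == g)[0] for g in grp_ids]
    grp_sizes = np.array([len(ix) for ix in grp_idx], float)
    ssd_wg = _ssd(D2, grp_idx)
    ssd_ag = ssd_total - ssd_wg
    ssd_ap_wg = ssd_wg - ssd_wp
    df_ag, df_ap = G - 1, P - G
    ms_ag = ssd_ag / df_ag
    ms_ap = ssd_ap_wg / df_ap if df_ap > 0 else 0.0

    # coefficients (Excoffier et al. 1992)
    sum_np2_over_ng = 0.0
    for g, gi in zip(grp_ids, grp_idx):
        sizes = [np.sum(pops[gi] == p) for p in np.unique(pops[gi])]
        sum_np2_over_ng += float(np.sum(np.array(sizes, float) ** 2)) / len(gi)
    n1 = (N - sum_np2_over_ng) / (P - G) if P > G else 1.0
    n2 = (sum_np2_over_ng - float(np.sum(pop_sizes**2)) / N) / (G - 1)
    n3 = (N - float(np.sum(grp_sizes**2)) / N) / (G - 1)

    sigma_b = (ms_ap - sigma_w) / n1 if P > G else 0.0
    sigma_a = (ms_ag - sigma_w - n2 * sigma_b) / n3
    comps = {
        "among_groups": sigma_a,
        "among_pops_within_groups": sigma_b,
        "within_pops": sigma_w,
    }
    df = {"among_groups": df_ag, "among_pops_within_groups": df_ap,
          "within_pops": df_wp}
    total = sigma_a + sigma_b + sigma_w
    phi = {
        "phi_st": (sigma_a + sigma_b) / total if total > 0 else 0.0,
        "phi_sc": sigma_b / (sigma_b + sigma_w) if (sigma_b + sigma_w) > 0 else 0.0,
        "phi_ct": sigma_a / total if total > 0 else 0.0,
    }
    return comps, df, phi


def amova(
    D: np.ndarray,
    populations: list[str] | np.ndarray,
    groups: list[str] | np.ndarray | None = None,
    permutations: int = 1000,
    seed=None,
    squared: bool = False,
) -> AmovaResult:
    """Hierarchical AMOVA on a distance matrix of pairwise difference counts.

    ``D`` is the sample-by-sample distance matrix (squared internally unless
    ``squared``); ``populations`` assigns each sample to a population and
    ``groups`` optionally to a higher-level group (taxon or region).
    Permutation schemes: Phi_ST permutes samples among populations, Phi_SC
    samples among populations within their group, Phi_CT whole populations
    among groups.
    """
    D = np.asarray(D, float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    D2 = D if squared else D * D
    pops = np.asarray(populations)
    grps = None if groups is None else np.asarray(groups)
    if len(np.unique(pops)) < 2:
        raise ValueError("need >= 2 populations")
    comps, df, phi = _amova_components(D2, pops, grps)
    total = sum(comps.values())
    pct = {k: 100.0 * v / total if total > 0 else 0.0 for k, v in comps.items()}

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = len(pops)
    hits = {k: 0 for k in phi}
    for _ in range(permutations):
        if grps is None:
            perm_pops = pops[rng.permutation(N)]
            _, _, ph = _amova_components(D2, perm_pops, None)
            if ph["phi_st"] >= phi["phi_st"] - 1e-12:
                hits["phi_st"] += 1
        else:
            # phi_st: samples among all populations (and their groups)
            order = rng.permutation(N)
            _, _, ph = _amova_components(D2, pops[order], grps[order])
            if ph["phi_st"] >= phi["phi_st"] - 1e-12:
                hits["phi_st"] += 1
            # phi_sc: samples among populations within their group
            perm_pops = pops.copy()
            for g in np.unique(grps):
                ii = np.where(grps == g)[0]
                perm_pops[ii] = pops[ii][rng.permutation(len(ii))]
            _, _, ph = _amova_components(D2, perm_pops, grps)
            if ph["phi_sc"] >= phi["phi_sc"] - 1e-12:
                hits["phi_sc"] += 1
            # phi_ct: whole populations among groups
            pop_ids = np.unique(pops)
            grp_of_pop = {p: grps[pops == p][0] for p in pop_ids}
            shuffled = rng.permutation([grp_of_pop[p] for p in pop_ids])
            new_map = dict(zip(pop_ids, shuffled))
            perm_grps = np.array([new_map[p] for p in pops])
            _, _, ph = _amova_components(D2, pops, perm_grps)
            if ph["phi_ct"] >= phi["phi_ct"] - 1e-12:
                hits["phi_ct"] += 1
    p_values = {k: (hits[k] + 1.0) / (permutations + 1.0) for k in phi}
    return AmovaResult(comps, pct, phi, p_values, df, permutations)


def pairwise_fst(
    D: np.ndarray,
    labels: list[str] | np.ndarray,
    permutations: int = 1000,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phi_ST-type F_ST between every pair of groups, with permutation p.

    Returns (fst_matrix, p_matrix) as group-by-group DataFrames.
    """
    labels = np.asarray(labels)
    ids = sorted(np.unique(labels))
    if len(ids) < 2:
        raise ValueError("need >= 2 groups")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fst = pd.DataFrame(0.0, index=ids, columns=ids)
    pv = pd.DataFrame(1.0, index=ids, columns=ids)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            ii = np.where((labels == ids[a]) | (labels == ids[b]))[0]
            res = amova(D[np.ix_(ii, ii)], labels[ii],
                        permutations=permutations, seed=rng)
            fst.iloc[a, b] = fst.iloc[b, a] = res.phi["phi_st"]
            pv.iloc[a, b] = pv.iloc[b, a] = res.p_values["phi_st"]
    return fst, pv


def fst_components(
    counts: np.ndarray,
    sizes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP among-deme and within-deme variance components (sigma_a,
    sigma_w) of the haploid variance partition; the multilocus ratio-of-sums
    F_ST is sum(sigma_a)/sum(sigma_a + sigma_w) over polymorphic SNPs."""
    counts = np.atleast_2d(np.asarray(counts, float))
    sizes = np.asarray(sizes, float)
    if sizes.ndim == 1:
        sizes = np.broadcast_to(sizes, counts.shape)
    N = sizes.sum(axis=1)
    C = counts.sum(axis=1)
    P = counts.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        ssd_total = C * (N - C) / N
        ssd_wp = np.sum(counts * (sizes - counts) / sizes, axis=1)
        ssd_ap = ssd_total - ssd_wp
        ms_ap = ssd_ap / (P - 1)
        ms_wp = ssd_wp / (N - P)
        n_prime = (N - np.sum(sizes**2, axis=1) / N) / (P - 1)
        sigma_a = (ms_ap - ms_wp) / n_prime
    poly = (C > 0) & (C < N)
    return (np.where(poly, sigma_a, np.nan),
            np.where(poly, ms_wp, np.nan))


def multilocus_fst(counts: np.ndarray, sizes: np.ndarray) -> float:
    """Weighted (ratio-of-sums) multilocus F_ST over a SNP count table."""
    sa, sw = fst_components(counts, sizes)
    ok = ~np.isnan(sa)
    den = float(np.nansum(sa[ok] + sw[ok]))
    return float(np.nansum(sa[ok])) / den if den > 0 else 0.0


def per_site_fst(
    counts: np.ndarray,
    sizes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Variance-partition F_ST and total expected heterozygosity per SNP.

    ``counts``: (S, d) derived/minor allele counts per deme; ``sizes``: (d,)
    haploid sample sizes (or (S, d) when they vary per site).  F_ST is the
    haploid one-level AMOVA Phi_ST computed in closed form from allele
    counts; H_e is the unbiased total expected heterozygosity.  Sites
    monomorphic over all demes get nan.
    """
    counts = np.atleast_2d(np.asarray(counts, float))
    sizes = np.asarray(sizes, float)
    if sizes.ndim == 1:
        sizes = np.broadcast_to(sizes, counts.shape)
    N = sizes.sum(axis=1)
    C = counts.sum(axis=1)
    P = counts.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        ssd_total = C * (N - C) / N
        ssd_wp = np.sum(counts * (sizes - counts) / sizes, axis=1)
        ssd_ap = ssd_total - ssd_wp
        ms_ap = ssd_ap / (P - 1)
        ms_wp = ssd_wp / (N - P)
        n_prime = (N - np.sum(sizes**2, axis=1) / N) / (P - 1)
        sigma_a = (ms_ap - ms_wp) / n_prime
        fst = sigma_a / (sigma_a + ms_wp)
        pbar = C / N
        he = N / (N - 1) * 2.0 * pbar * (1.0 - pbar)
    poly = (C > 0) & (C < N)
    fst = np.where(poly, fst, np.nan)
    he = np.where(poly, he, np.nan)
    return fst, he


# --- S_nn --------------------------------------------------------------------


@dataclass
class SnnResult:
    snn: float
    p_value: float
    permutations: int


def _nn_mask(D: np.ndarray) -> np.ndarray:
    """Boolean matrix marking each sample's nearest neighbours (self
    excluded; distance ties all marked)."""
    n = D.shape[0]
    Dx = D.astype(float).copy()
    np.fill_diagonal(Dx, np.inf)
    dmin = Dx.min(axis=1)
    return Dx <= dmin[:, None] + 1e-12


def snn_statistic(D: np.ndarray, labels: np.ndarray,
                  nn: np.ndarray | None = None) -> float:
    """Hudson (2000) S_nn: mean over samples of the fraction of nearest
    neighbours (minimum distance; ties split equally) sharing the label."""
    labels = np.asarray(labels)
    if nn is None:
        nn = _nn_mask(np.asarray(D, float))
    same = labels[:, None] == labels[None, :]
    frac = (nn & same).sum(axis=1) / nn.sum(axis=1)
    return float(frac.mean())


def snn(
    D: np.ndarray,
    labels: list[str] | np.ndarray,
    permutations: int = 1000,
    seed=None,
) -> SnnResult:
    """S_nn with a label-permutation p-value, p = Pr(S_nn_perm >= observed)."""
    labels = np.asarray(labels)
    ids, cnt = np.unique(labels, return_counts=True)
    if len(ids) < 2 or cnt.min() < 2:
        raise ValueError("S_nn needs >= 2 groups with >= 2 samples each")
    nn = _nn_mask(np.asarray(D, float))
    obs = snn_statistic(D, labels, nn=nn)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = labels[rng.permutation(len(labels))]
        if snn_statistic(D, perm, nn=nn) >= obs - 1e-12:
            hits += 1
    return SnnResult(obs, (hits + 1.0) / (permutations + 1.0), permutations)


# --- PCoA --------------------------------------------------------------------


@dataclass
class PcoaResult:
    coordinates: np.ndarray  # (n, k) scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    pct_variance: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(D: np.ndarray) -> PcoaResult:
    """Principal coordinate analysis by Gower double-centering.

    B = -1/2 J D^2 J; coordinates are eigenvectors scaled by sqrt(lambda);
    percent variance uses the positive eigenvalues only, negatives are
    reported and dropped.
    """
    D = np.asarray(D, float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals).max(), 1.0) * 1e-10
    pos = vals > tol
    neg = vals < -tol
    lam = vals[pos]
    coords = vecs[:, pos] * np.sqrt(lam)
    pct = 100.0 * lam / lam.sum() if lam.size else np.array([])
    return PcoaResult(coords, lam, pct, vals[neg])


# --- haplotype minimum spanning network -------------------------------------


def haplotype_msn(
    haplotypes: list[str],
    frequencies: dict[str, dict[str, int]] | None = None,
):
    """Minimum spanning network of haplotypes.

    Edges are weighted by pairwise difference counts; the network is the
    union of all minimum spanning trees (Kruskal by weight class, keeping
    every co-minimal edge that joined two components at its class start).
    ``frequencies`` optionally annotates nodes with per-group counts.
    Returns a ``networkx.Graph``.
    """
    import networkx as nx

    H = len(haplotypes)
    if H < 2:
        raise ValueError("need >= 2 haplotypes")
    edges = []
    for i in range(H):
        for j in range(i + 1, H):
            a, b = haplotypes[i], haplotypes[j]
            if len(a) != len(b):
                raise ValueError("haplotypes must be aligned (equal length)")
            d = sum(1 for x, y in zip(a, b) if x != y)
            edges.append((d, i, j))
    edges.sort()
    parent = list(range(H))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    G = nx.Graph()
    for i, h in enumerate(haplotypes):
        attrs = {"haplotype": h}
        if frequencies is not None:
            attrs["freq"] = frequencies.get(h, {})
        G.add_node(i, **attrs)
    k = 0
    while k < len(edges):
        w = edges[k][0]
        cls = []
        while k < len(edges) and edges[k][0] == w:
            cls.append(edges[k])
            k += 1
        # evaluate all class edges against components at class start
        keep = [(i, j) for _, i, j in cls if find(i) != find(j)]
        for i, j in keep:
            G.add_edge(i, j, weight=w)
        for i, j in keep:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return G
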