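"""Between-group divergence statistics.

d_xy (mean between-group pairwise difference per compared site, pairwise
deletion), Nei's net divergence d_a = d_xy - (pi_1 + pi_2)/2, shared /
exclusive / fixed polymorphic sites, haplotype sharing, and Jukes-Cantor net
distances between populations over concatenated SNP columns (the PCoA input).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import HaplotypeSet, LocusAlignment, build_variant_table

__all__ = [
    "net_divergence",
    "polymorphism_sharing",
    "haplotype_sharing",
    "jc_distance",
    "jc_population_distance",
    "concatenated_snp_matrix",
]

_BASES = frozenset("ACGT")


def _codes(mat: np.ndarray) -> np.ndarray:
    """Map characters to int8 codes (A..T = 0..3, everything else -1)."""
    out = np.full(mat.shape, -1, dtype=np.int8)
    for code, b in enumerate("ACGT"):
        out[mat == b] = code
    return out


def _pairwise_p(rows: np.ndarray, rows2: np.ndarray | None = None) -> np.ndarray:
    """Per-pair p-distances (pairwise deletion); within-group pairs when
    ``rows2`` is None, otherwise all between-group pairs.  nan for pairs with
    no jointly called site."""
    c1 = _codes(rows)
    vals = []
    if rows2 is None:
        for i in range(len(c1)):
            a = c1[i]
            sub = c1[i + 1:]
            both = (a >= 0) & (sub >= 0)
            nc = both.sum(axis=1)
            diff = ((a != sub) & both).sum(axis=1)
            with np.errstate(invalid="ignore"):
                vals.append(np.where(nc > 0, diff / np.maximum(nc, 1), np.nan))
    else:
        c2 = _codes(rows2)
        for i in range(len(c1)):
            a = c1[i]
            both = (a >= 0) & (c2 >= 0)
            nc = both.sum(axis=1)
            diff = ((a != c2) & both).sum(axis=1)
            with np.errstate(invalid="ignore"):
                vals.append(np.where(nc > 0, diff / np.maximum(nc, 1), np.nan))
    return np.concatenate(vals) if vals else np.array([])


def _mean_pairwise(rows: np.ndarray, rows2: np.ndarray | None = None) -> float:
    vals = _pairwise_p(rows, rows2)
    vals = vals[~np.isnan(vals)]
    return float(np.mean(vals)) if vals.size else 0.0


def net_divergence(
    aln: LocusAlignment,
    group1: Sequence[str],
    group2: Sequence[str] | None,
    allow_single_group2: bool = False,
) -> tuple[float, float]:
    """(d_xy, d_a) per site between two sample groups at one locus.

    ``group2=None`` with ``allow_single_group2`` uses the aligned outgroup row
    as a single-sequence group (pi_outgroup taken as 0 — a logged caveat for
    outgroup comparisons, since within-group diversity of a single sequence is
    unobservable).
    """
    m1 = aln.rows(group1)
    if group2 is None:
        if aln.outgroup is None:
            raise ValueError(f"locus {aln.locus_id}: no outgroup row")
        m2 = aln.outgroup[None, :]
        pi2 = 0.0
        single_ok = True
    else:
        m2 = aln.rows(group2)
        single_ok = allow_single_group2
        pi2 = None
    if len(m1) < 2 or (len(m2) < 2 and not single_ok):
        raise ValueError("net divergence needs >= 2 samples per group")
    dxy = _mean_pairwise(m1, m2)
    pi1 = _mean_pairwise(m1)
    if pi2 is None:
        pi2 = _mean_pairwise(m2) if len(m2) >= 2 else 0.0
    return dxy, dxy - (pi1 + pi2) / 2.0


def polymorphism_sharing(
    aln: LocusAlignment,
    group1: Sequence[str],
    group2: Sequence[str],
    include_indels: bool = True,
) -> dict[str, int]:
    """Counts of shared / exclusive / fixed polymorphic sites between groups.

    SNP and indel polymorphisms come from :func:`build_variant_table` on each
    group (indel events collapse gap runs); shared = polymorphic in both,
    exclusive = polymorphic in exactly one.  Fixed differences are alignment
    columns where both groups are monomorphic for different states (gap
    counted as a state, per column — SITES convention).
    """
    vt1 = build_variant_table(aln, group1, include_indels=include_indels)
    vt2 = build_variant_table(aln, group2, include_indels=include_indels)
    if vt1.L_total != vt2.L_total:
        raise ValueError("variant tables from different coordinates")
    key1 = {(r.position, r.type) for r in vt1.sites.itertuples(index=False)}
    key2 = {(r.position, r.type) for r in vt2.sites.itertuples(index=False)}
    shared = len(key1 & key2)
    ex1 = len(key1 - key2)
    ex2 = len(key2 - key1)
    m1, m2 = aln.rows(group1), aln.rows(group2)
    fixed = 0
    for j in range(aln.length):
        s1 = {c for c in m1[:, j] if c != "N"}
        s2 = {c for c in m2[:, j] if c != "N"}
        if len(s1) == 1 and len(s2) == 1 and s1 != s2:
            fixed += 1
    return {
        "shared": shared,
        "exclusive_1": ex1,
        "exclusive_2": ex2,
        "fixed": fixed,
    }


def haplotype_sharing(hs1: HaplotypeSet, hs2: HaplotypeSet) -> dict[str, float]:
    """Shared and unique haplotype counts between two groups at one locus,
    with the percentage of each group's haplotype pool that is unique."""
    if hs1.locus_id != hs2.locus_id:
        raise ValueError("haplotype sets from different loci")
    set1, set2 = set(hs1.haplotypes), set(hs2.haplotypes)
    shared = len(set1 & set2)
    u1, u2 = len(set1 - set2), len(set2 - set1)
    return {
        "shared": shared,
        "unique_1": u1,
        "unique_2": u2,
        "pct_unique_1": 100.0 * u1 / len(set1),
        "pct_unique_2": 100.0 * u2 / len(set2),
    }


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p)."""
    if p >= 0.75:
        raise ValueError(f"p-distance {p} >= 0.75: JC distance undefined")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def concatenated_snp_matrix(
    alignments: Iterable[LocusAlignment],
    sample_ids: Sequence[str],
) -> np.ndarray:
    """Character matrix of all SNP columns across loci for ``sample_ids``
    (N where a sample is absent from a locus)."""
    cols = []
    for aln in alignments:
        present = [s for s in sample_ids if s in set(aln.sample_ids)]
        if len(present) < 2:
            continue
        vt = build_variant_table(aln, present, include_indels=False)
        sub = aln.rows(present)
        pos = vt.sites["position"].to_numpy()
        if len(pos) == 0:
            continue
        block = np.full((len(sample_ids), len(pos)), "N", dtype="U1")
        row_of = {s: i for i, s in enumerate(aln.subset_ids(present))}
        for si, s in enumerate(sample_ids):
            if s in row_of:
                block[si] = sub[row_of[s]][pos]
        cols.append(block)
    if not cols:
        return np.zeros((len(sample_ids), 0), dtype="U1")
    return np.concatenate(cols, axis=1)


def jc_population_distance(
    alignments: Iterable[LocusAlignment],
    populations: dict[str, Sequence[str]],
) -> pd.DataFrame:
    """Net Jukes-Cantor distance matrix between populations.

    Pairwise sample distances are JC-corrected p-distances over all SNP
    columns concatenated across loci (pairwise deletion); the net distance
    between two populations subtracts the average of the two within-
    population means from the between-population mean.
    """
    pops = sorted(populations)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    sample_ids = [s for p in pops for s in populations[p]]
    mat = concatenated_snp_matrix(alignments, sample_ids)
    n = len(sample_ids)
    codes = _codes(mat)
    D = np.zeros((n, n))
    for i in range(n):
        a = codes[i]
        sub = codes[i + 1:]
        both = (a >= 0) & (sub >= 0)
        nc = both.sum(axis=1)
        diff = ((a != sub) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(nc > 0, diff / np.maximum(nc, 1), 0.0)
        for k, j in enumerate(range(i + 1, n)):
            try:
                D[i, j] = D[j, i] = jc_distance(float(p[k]))
            except ValueError as exc:
                raise ValueError(
                    f"samples {sample_ids[i]}/{sample_ids[j]}: {exc}"
                ) from exc
    idx = {}
    start = 0
    for p in pops:
        idx[p] = list(range(start, start + len(populations[p])))
        start += len(populations[p])

    def within(p: str) -> float:
        ii = idx[p]
        if len(ii) < 2:
            return 0.0
        vals = [D[a, b] for k, a in enumerate(ii) for b in ii[k + 1:]]
        return float(np.mean(vals))

    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            ii, jj = idx[pops[a]], idx[pops[b]]
            between = float(np.mean([D[x, y] for x in ii for y in jj]))
            net = between - (within(pops[a]) + within(pops[b])) / 2.0
            out.iloc[a, b] = out.iloc[b, a] = net
    return out
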