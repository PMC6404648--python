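"""Numba-compiled finite-island coalescent for single-SNP null envelopes.

Same model as :func:`pinepop.coalescent.simulate_island` (time in 4N-deme
units, per-deme pair coalescence rate 2, per-lineage migration M/2) but
specialised: each replicate returns the per-group derived-allele count of one
mutation placed on the genealogy proportional to branch length.  The pure-
Python engine is the reference implementation; tests compare the two
distributionally.

Exact event aggregation: demes are exchangeable, so a migration that moves a
lineage which is *alone* in its deme into an *empty* deme changes nothing —
only moves into occupied demes, moves out of shared demes, and coalescences
are simulated.  A lone lineage therefore migrates effectively at rate
(M/2) * (occupied-1)/(d-1) instead of M/2, which removes the vast majority
of events when few of the d demes are sampled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["island_snp_counts"]


@njit(cache=True)
def _one_rep(d, M, group_sizes):
    n = 0
    G = group_sizes.shape[0]
    for g in range(G):
        n += group_sizes[g]
    n_nodes = 2 * n - 1
    leaf = np.zeros((n_nodes, G), dtype=np.int64)
    start = 0
    for g in range(G):
        for i in range(group_sizes[g]):
            leaf[start + i, g] = 1
        start += group_sizes[g]
    time = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)

    lin_node = np.arange(n)
    lin_deme = np.empty(n, dtype=np.int64)
    start = 0
    for g in range(G):
        for i in range(group_sizes[g]):
            lin_deme[start + i] = g
        start += group_sizes[g]
    occ = np.zeros(d, dtype=np.int64)
    for i in range(n):
        occ[lin_deme[i]] += 1
    k = n
    t = 0.0
    nxt = n
    while k > 1:
        # classify demes / lineages
        coal_total = 0.0
        n_occ = 0
        n_co = 0  # lineages sharing a deme
        for dd in range(d):
            c = occ[dd]
            if c > 0:
                n_occ += 1
                if c >= 2:
                    coal_total += c * (c - 1)
                    n_co += c
        n_single = k - n_co
        # effective migration rates (futile single->empty moves skipped)
        rate_co = M / 2.0 * n_co
        rate_single = 0.0
        if n_occ > 1:
            rate_single = M / 2.0 * n_single * (n_occ - 1.0) / (d - 1.0)
        total = coal_total + rate_co + rate_single
        t += np.random.exponential(1.0 / total)
        r = np.random.random() * total
        if r < coal_total:
            acc = 0.0
            deme = -1
            for dd in range(d):
                c = occ[dd]
                if c >= 2:
                    acc += c * (c - 1)
                    if r < acc:
                        deme = dd
                        break
            c = occ[deme]
            i1 = np.random.randint(c)
            i2 = np.random.randint(c - 1)
            if i2 >= i1:
                i2 += 1
            a = -1
            b = -1
            seen = 0
            for i in range(k):
                if lin_deme[i] == deme:
                    if seen == i1:
                        a = i
                    if seen == i2:
                        b = i
                    seen += 1
            na, nb = lin_node[a], lin_node[b]
            parent[na] = nxt
            parent[nb] = nxt
            time[nxt] = t
            for g in range(G):
                leaf[nxt, g] = leaf[na, g] + leaf[nb, g]
            lin_node[a] = nxt
            lin_node[b] = lin_node[k - 1]
            lin_deme[b] = lin_deme[k - 1]
            nxt += 1
            occ[deme] -= 1
            k -= 1
        elif r < coal_total + rate_co:
            # a colocated lineage moves; destination empty or occupied
            pick = np.random.randint(n_co)
            i = -1
            seen = 0
            for j in range(k):
                if occ[lin_deme[j]] >= 2:
                    if seen == pick:
                        i = j
                        break
                    seen += 1
            src_d = lin_deme[i]
            occ[src_d] -= 1
            if np.random.random() * (d - 1.0) < (d - n_occ):
                # to an empty deme
                dest = -1
                for dd in range(d):
                    if occ[dd] == 0 and dd != src_d:
                        dest = dd
                        break
                lin_deme[i] = dest
                occ[dest] += 1
            else:
                # to another occupied deme (uniform among them, not src)
                n_t = 0
                for dd in range(d):
                    if occ[dd] > 0 and dd != src_d:
                        n_t += 1
                if n_t == 0:
                    occ[src_d] += 1  # nowhere to go; undo
                else:
                    pickd = np.random.randint(n_t)
                    seen = 0
                    for dd in range(d):
                        if occ[dd] > 0 and dd != src_d:
                            if seen == pickd:
                                lin_deme[i] = dd
                                occ[dd] += 1
                                break
                            seen += 1
        else:
            # a lone lineage joins another occupied deme
            pick = np.random.randint(n_single)
            i = -1
            seen = 0
            for j in range(k):
                if occ[lin_deme[j]] == 1:
                    if seen == pick:
                        i = j
                        break
                    seen += 1
            src_d = lin_deme[i]
            occ[src_d] -= 1
            n_t = 0
            for dd in range(d):
                if occ[dd] > 0 and dd != src_d:
                    n_t += 1
            pickd = np.random.randint(n_t)
            seen = 0
            for dd in range(d):
                if occ[dd] > 0 and dd != src_d:
                    if seen == pickd:
                        lin_deme[i] = dd
                        occ[dd] += 1
                        break
                    seen += 1
    # choose branch proportional to length (root excluded)
    total_len = 0.0
    for u in range(n_nodes):
        if parent[u] >= 0:
            total_len += time[parent[u]] - time[u]
    r = np.random.random() * total_len
    acc = 0.0
    out = np.zeros(G, dtype=np.int64)
    for u in range(n_nodes):
        if parent[u] >= 0:
            acc += time[parent[u]] - time[u]
            if r < acc:
                for g in range(G):
                    out[g] = leaf[u, g]
                break
    return out


@njit(cache=True)
def _run(d, M, group_sizes, reps, seed):
    np.random.seed(seed)
    out = np.empty((reps, group_sizes.shape[0]), dtype=np.int64)
    for r in range(reps):
        out[r] = _one_rep(d, M, group_sizes)
    return out


def island_snp_counts(
    demes: int, M: float, sample_sizes, reps: int, seed: int
) -> np.ndarray:
    """Derived-allele counts per sampled group for ``reps`` single-SNP island-
    model loci (each sampled group in its own deme)."""
    sizes = np.asarray(sample_sizes, dtype=np.int64)
    if len(sizes) > demes:
        raise ValueError("more sampled groups than demes")
    if M <= 0:
        raise ValueError("island model needs M > 0")
    return _run(int(demes), float(M), sizes, int(reps), int(seed) % 2**31)
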