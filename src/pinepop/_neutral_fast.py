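"""Numba-compiled panmictic neutral simulator for null banks.

Per replicate: one n-coalescent genealogy, infinite-sites mutations
(fixed-theta or fixed-S), and the summary tuple (S, theta_pi, theta_L, F)
from which Tajima's D, normalized Fay-Wu H and the Ewens-Watterson
homozygosity are reassembled.  The pure-Python path in
:mod:`pinepop.neutrality` is the reference implementation; tests compare the
two distributionally.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["neutral_reps"]


@njit(cache=True)
def _run(n, reps, theta, fixed_S, seed):
    np.random.seed(seed)
    n_nodes = 2 * n - 1
    out = np.empty((reps, 5))
    parent = np.empty(n_nodes, dtype=np.int64)
    time = np.empty(n_nodes)
    active = np.empty(n_nodes, dtype=np.int64)
    desc = np.zeros((n_nodes, n), dtype=np.bool_)
    for r in range(reps):
        for i in range(n_nodes):
            parent[i] = -1
            time[i] = 0.0
        k = n
        for i in range(n):
            active[i] = i
        t = 0.0
        nxt = n
        while k > 1:
            t += np.random.exponential(1.0 / (k * (k - 1)))
            i1 = np.random.randint(k)
            i2 = np.random.randint(k - 1)
            if i2 >= i1:
                i2 += 1
            a, b = active[i1], active[i2]
            parent[a] = nxt
            parent[b] = nxt
            time[nxt] = t
            lo, hi = (i1, i2) if i1 < i2 else (i2, i1)
            active[lo] = nxt
            active[hi] = active[k - 1]
            nxt += 1
            k -= 1
        # descendant leaf sets (children created before parents)
        for u in range(n_nodes):
            for i in range(n):
                desc[u, i] = False
        for i in range(n):
            desc[i, i] = True
        for u in range(n_nodes - 1):
            p = parent[u]
            if p >= 0:
                for i in range(n):
                    if desc[u, i]:
                        desc[p, i] = True
        # branch lengths and total
        total_len = 0.0
        for u in range(n_nodes):
            if parent[u] >= 0:
                total_len += time[parent[u]] - time[u]
        if fixed_S >= 0:
            nmut = fixed_S
        else:
            nmut = np.random.poisson(theta * total_len)
        if nmut == 0:
            out[r, 0] = 0.0
            out[r, 1] = 0.0
            out[r, 2] = 0.0
            out[r, 3] = 1.0
            out[r, 4] = 1.0
            continue
        tp = 0.0
        tl = 0.0
        h = np.zeros(n, dtype=np.int64)
        for m in range(nmut):
            rr = np.random.random() * total_len
            acc = 0.0
            br = -1
            for u in range(n_nodes):
                if parent[u] >= 0:
                    acc += time[parent[u]] - time[u]
                    if rr < acc:
                        br = u
                        break
            xi = 0
            for i in range(n):
                if desc[br, i]:
                    xi += 1
                    h[i] = h[i] * np.int64(1315423911) + np.int64(br + 1)
            tp += 2.0 * xi * (n - xi) / (n * (n - 1.0))
            tl += xi / (n - 1.0)
        hs = np.sort(h)
        F = 0.0
        k_hap = 1
        run = 1
        for i in range(1, n):
            if hs[i] == hs[i - 1]:
                run += 1
            else:
                F += run * run
                run = 1
                k_hap += 1
        F += run * run
        out[r, 0] = nmut
        out[r, 1] = tp
        out[r, 2] = tl
        out[r, 3] = F / (n * n)
        out[r, 4] = k_hap
    return out


def neutral_reps(
    n: int, reps: int, theta: float | None = None, S: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """(reps, 5) array of (S, theta_pi, theta_L, F, k_hap) replicates."""
    if (theta is None) == (S is None):
        raise ValueError("give exactly one of theta or S")
    fixed_S = -1 if S is None else int(S)
    th = 0.0 if theta is None else float(theta)
    return _run(int(n), int(reps), th, fixed_S, int(seed) % 2**31)
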