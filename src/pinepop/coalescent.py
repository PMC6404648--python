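"""Neutral coalescent simulation for null distributions and synthetic studies.

Conventions (ms-style): time is measured in units of 4N generations, so a
pair of lineages in one (sub)population coalesces at rate 2 and E[TMRCA] for
n=2 is 0.5.  theta = 4*N*mu and rho = 4*N*c are locus-total rates; with tree
length measured in these units the expected number of segregating sites is
E[S] = theta * a_{n-1}.  Migration M = 4*N*m moves each lineage at rate M/2.

All randomness flows through an explicit ``numpy.random.Generator`` or seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Genealogy",
    "SimulatedLocus",
    "simulate_genealogy",
    "simulate_island",
    "simulate_split",
    "mutate_infinite_sites",
    "simulate_with_recombination",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class Genealogy:
    """Binary coalescent tree over ``n`` leaves (nodes ``0..2n-2``).

    ``parent[i]`` is -1 for the root; ``time[i]`` is the node age in 4N
    units (leaves at 0).  ``deme`` optionally labels each leaf with the
    population it was sampled from.
    """

    n: int
    parent: np.ndarray
    time: np.ndarray
    children: list[tuple[int, int]] = field(default_factory=list)
    deme: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return 2 * self.n - 1

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (root gets 0)."""
        bl = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                bl[i] = self.time[p] - self.time[i]
        return bl

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_masks(self) -> list[int]:
        """Bitmask of descendant leaves per node (leaf i -> bit i)."""
        masks = [0] * self.n_nodes
        for i in range(self.n):
            masks[i] = 1 << i
        for i in np.argsort(self.time, kind="stable"):
            p = self.parent[i]
            if p >= 0:
                masks[p] |= masks[int(i)]
        return masks

    def to_newick(self, labels: list[str] | None = None) -> str:
        labels = labels or [f"s{i}" for i in range(self.n)]
        kids: dict[int, list[int]] = {}
        for i in range(self.n_nodes):
            p = int(self.parent[i])
            if p >= 0:
                kids.setdefault(p, []).append(i)

        def rec(node: int) -> str:
            p = int(self.parent[node])
            bl = self.time[p] - self.time[node] if p >= 0 else 0.0
            if node < self.n:
                return f"{labels[node]}:{bl:.6f}"
            inner = ",".join(rec(c) for c in kids[node])
            return f"({inner}):{bl:.6f}"

        return rec(self.root) + ";"


def simulate_genealogy(n: int, seed=None) -> Genealogy:
    """Standard panmictic n-coalescent: while k lineages remain the waiting
    time is Exponential(rate k(k-1)) in 4N units and a uniform pair merges."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = _rng(seed)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    children = []
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        children.append((a, b))
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Genealogy(n, parent, time, children)


def _structured_coalescent(
    deme_of: list[int],
    n_demes: int,
    M: float,
    rng: np.random.Generator,
    merges: list[tuple[float, int, int]] | None = None,
    group_of: dict[int, int] | None = None,
) -> Genealogy:
    """Coalescent with symmetric island migration and scheduled deme merges.

    ``merges`` entries (t, dest, src) move every lineage in deme ``src`` into
    ``dest`` at time ``t`` and remove ``src`` from the migration target set.
    ``group_of`` optionally restricts migration to demes of the same group
    (e.g. populations within one taxon); lineages whose group has a single
    alive deme cannot migrate.
    """
    n = len(deme_of)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    lineages = list(range(n))
    lin_deme = list(deme_of)
    alive_demes = set(range(n_demes))
    if group_of is None:
        group_of = {d: 0 for d in range(n_demes)}
    # stable sort on time only: ties apply in the order given (population
    # collapses must precede the taxon-level merge at the same split time)
    merges = sorted(merges or [], key=lambda m: m[0])
    mi = 0
    t = 0.0
    nxt = n
    def apply_merge() -> None:
        nonlocal lin_deme, mi, t
        mt, dest, src = merges[mi]
        t = mt
        lin_deme = [dest if d == src else d for d in lin_deme]
        alive_demes.discard(src)
        alive_demes.add(dest)
        mi += 1

    while len(lineages) > 1:
        k = len(lineages)
        counts: dict[int, int] = {}
        for d in lin_deme:
            counts[d] = counts.get(d, 0) + 1
        coal_rates = {d: c * (c - 1) for d, c in counts.items() if c >= 2}
        coal_total = sum(coal_rates.values())
        alive_per_group: dict[int, int] = {}
        for d in alive_demes:
            g = group_of.get(d, 0)
            alive_per_group[g] = alive_per_group.get(g, 0) + 1
        eligible = [i for i, d in enumerate(lin_deme)
                    if alive_per_group.get(group_of.get(d, 0), 0) > 1]
        mig_total = len(eligible) * M / 2.0 if M > 0 else 0.0
        total = coal_total + mig_total
        if total == 0.0:
            if mi >= len(merges):
                raise ValueError(
                    "no common ancestor reachable: M=0 with lineages in "
                    "multiple demes and no pending splits"
                )
            apply_merge()
            continue
        t_event = t + rng.exponential(1.0 / total)
        if mi < len(merges) and merges[mi][0] <= t_event:
            apply_merge()
            continue
        t = t_event
        if rng.random() * total < coal_total:
            demes = list(coal_rates)
            weights = np.array([coal_rates[d] for d in demes], float)
            d = demes[rng.choice(len(demes), p=weights / weights.sum())]
            idx = [i for i, dd in enumerate(lin_deme) if dd == d]
            i1, i2 = rng.choice(len(idx), size=2, replace=False)
            a, b = lineages[idx[i1]], lineages[idx[i2]]
            parent[a] = parent[b] = nxt
            time[nxt] = t
            drop = {idx[i1], idx[i2]}
            keep = [i for i in range(k) if i not in drop]
            lineages = [lineages[i] for i in keep] + [nxt]
            lin_deme = [lin_deme[i] for i in keep] + [d]
            nxt += 1
        else:
            i = eligible[int(rng.integers(len(eligible)))]
            g = group_of.get(lin_deme[i], 0)
            targets = [d for d in alive_demes
                       if d != lin_deme[i] and group_of.get(d, 0) == g]
            lin_deme[i] = targets[int(rng.integers(len(targets)))]
    return Genealogy(len(deme_of), parent, time, deme=np.array(deme_of))


def simulate_island(
    d: int,
    M: float,
    samples_per_deme: list[int] | dict[int, int],
    seed=None,
) -> Genealogy:
    """Finite-island structured coalescent: ``d`` demes, migration M = 4Nm
    (per-lineage rate M/2), per-deme pair coalescence rate 2.

    ``samples_per_deme`` may be a list of counts for demes 0..len-1 (demes
    beyond the list are unsampled) or a {deme: count} dict.
    """
    if d < 2:
        raise ValueError("island model needs d >= 2")
    if isinstance(samples_per_deme, dict):
        counts = samples_per_deme
    else:
        counts = {i: c for i, c in enumerate(samples_per_deme)}
    if any(k >= d or k < 0 for k in counts):
        raise ValueError("sampled deme index outside 0..d-1")
    deme_of: list[int] = []
    for deme in sorted(counts):
        deme_of.extend([deme] * counts[deme])
    if len(deme_of) < 2:
        raise ValueError("need >= 2 sampled lineages")
    occupied = {dd for dd in deme_of}
    if M == 0 and len(occupied) > 1:
        raise ValueError("M=0 with samples in multiple demes never coalesces")
    return _structured_coalescent(deme_of, d, M, _rng(seed))


def simulate_split(
    split_events: list[tuple[float, int, int]],
    samples_per_pop: dict[int, int],
    M: float = 0.0,
    seed=None,
) -> Genealogy:
    """Population-split coalescent.

    ``split_events`` is a list of (time_4N, dest, src): looking backward in
    time, population ``src`` merges into ``dest`` at that time.  Optional
    symmetric migration M among extant populations before their merges.
    """
    pops = sorted(samples_per_pop)
    event_pops = {p for _, a, b in split_events for p in (a, b)}
    if not set(pops) <= event_pops | set(pops):
        raise ValueError("inconsistent population labels")
    for t, _, _ in split_events:
        if t <= 0:
            raise ValueError("split times must be positive")
    deme_of = []
    for p in pops:
        deme_of.extend([p] * samples_per_pop[p])
    if len(deme_of) < 2:
        raise ValueError("need >= 2 sampled lineages")
    n_demes = max(max(pops), max((max(a, b) for _, a, b in split_events), default=0)) + 1
    if M == 0.0 and len(set(deme_of)) > 1 and not split_events:
        raise ValueError("multiple populations need migration or split events")
    return _structured_coalescent(deme_of, n_demes, M, _rng(seed), merges=split_events)


def simulate_structured(
    deme_of: list[int],
    n_demes: int,
    M: float,
    merges: list[tuple[float, int, int]] | None = None,
    group_of: dict[int, int] | None = None,
    seed=None,
) -> Genealogy:
    """General structured coalescent: arbitrary deme assignment, migration
    groups and scheduled deme merges (the synthetic-study workhorse)."""
    return _structured_coalescent(
        list(deme_of), n_demes, M, _rng(seed), merges=merges, group_of=group_of
    )


@dataclass
class SimulatedLocus:
    """Infinite-sites output: derived-allele matrix and site positions."""

    matrix: np.ndarray  # (n, S) 0/1, 1 = derived
    positions: np.ndarray  # alignment columns, strictly increasing
    genealogy: Genealogy
    L: int

    @property
    def S(self) -> int:
        return self.matrix.shape[1]


def mutate_infinite_sites(
    g: Genealogy,
    L: int,
    theta: float | None = None,
    S: int | None = None,
    seed=None,
) -> SimulatedLocus:
    """Drop infinite-sites mutations on a genealogy.

    Exactly one of ``theta`` (fixed-theta: the mutation count is
    Poisson(theta * total tree length), locus-total theta, 4N-unit lengths,
    giving E[S] = theta * a_{n-1}) or ``S`` (fixed-S conditioning: exactly S
    mutations placed with probability proportional to branch length) must be
    given.  Each mutation occupies a distinct uniformly drawn column of the
    ``L``-bp locus.
    """
    if (theta is None) == (S is None):
        raise ValueError("give exactly one of theta or S")
    rng = _rng(seed)
    bl = g.branch_lengths()
    total = bl.sum()
    if theta is not None:
        if theta < 0:
            raise ValueError("theta must be >= 0")
        nmut = int(rng.poisson(theta * total)) if theta > 0 else 0
    else:
        if S < 0:
            raise ValueError("S must be >= 0")
        nmut = int(S)
    if nmut > L:
        raise ValueError(f"{nmut} mutations exceed locus length {L} (infinite sites)")
    if nmut == 0:
        return SimulatedLocus(
            np.zeros((g.n, 0), dtype=np.int8), np.array([], dtype=int), g, L
        )
    probs = bl / total
    branches = rng.choice(g.n_nodes, size=nmut, p=probs)
    positions = np.sort(rng.choice(L, size=nmut, replace=False))
    masks = g.leaf_masks()
    mat = np.zeros((g.n, nmut), dtype=np.int8)
    order = rng.permutation(nmut)  # branch draw order independent of position
    for col, b in zip(order, branches):
        m = masks[int(b)]
        for leaf in range(g.n):
            if m >> leaf & 1:
                mat[leaf, col] = 1
    return SimulatedLocus(mat, positions, g, L)


def simulate_with_recombination(
    n: int,
    theta: float,
    rho: float,
    L: int,
    seed=None,
) -> SimulatedLocus:
    """Haplotypes under the neutral coalescent with intralocus recombination
    (Hudson ancestral recombination graph, via msprime).

    Guarded to desk scale: n <= 30 and rho <= 50.  Locus-total theta and rho,
    ms scaling (time in 4N units): msprime is run with haploid samples and
    population size 1/2 so one msprime generation equals 4N generations.
    """
    if n > 30 or rho > 50:
        raise ValueError("desk-scale guard: need n <= 30 and rho <= 50")
    if rho < 0 or theta < 0:
        raise ValueError("rates must be >= 0")
    import msprime

    seed_int = None
    if seed is not None:
        seed_int = int(_rng(seed).integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=0.5,
        sequence_length=L,
        recombination_rate=rho / L,
        random_seed=seed_int,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=theta / L,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed_int,
    )
    positions = []
    cols = []
    for var in mts.variants():
        geno = np.asarray(var.genotypes, dtype=np.int8)
        if geno.min() == geno.max():
            continue
        positions.append(var.site.position)
        cols.append((geno != 0).astype(np.int8))
    if cols:
        mat = np.column_stack(cols)
        pos = np.array([int(p) for p in positions])
        # map continuous positions to distinct integer columns
        pos = np.arange(len(pos)) if len(np.unique(pos)) < len(pos) else pos
    else:
        mat = np.zeros((n, 0), dtype=np.int8)
        pos = np.array([], dtype=int)
    first_tree = ts.first()
    g = Genealogy(
        n,
        np.array([first_tree.parent(u) if first_tree.parent(u) != -1 else -1
                  for u in range(ts.num_nodes)]),
        np.array([ts.node(u).time for u in range(ts.num_nodes)]),
    )
    return SimulatedLocus(mat, pos, g, L)
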