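"""Synthetic paper-shaped studies with known truth.

Generates complete studies shaped like the pine-taxa design: three recently
diverged taxa (haploid sample sizes 79/24/50 across 16 populations),
79 nuclear gene fragments (~420 bp each, ~33 kbp total), three non-
recombining mtDNA fragments with stronger structure, and a deeply diverged
outgroup sequence per locus.  Each locus is simulated under a split-plus-
island coalescent (populations are island demes within their taxon; taxa
merge backward at recent split times; the outgroup lineage joins far in the
past), so shared ancestral polymorphism, weak net divergence and negative
Tajima's D arise mechanistically rather than by construction.

Default parameters target the study's observed regime: per-site theta
log-normal around 0.004-0.005, taxon split times of a few hundredths of 4N
generations (shared polymorphism well above half, net divergence below
0.001), and an outgroup join time giving net outgroup divergence near 0.024.

``inject_selection`` adds stylized post-hoc selection signals (divergent
allele-frequency shifts or sweep-like SFS surgery) with exact truth labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalescent import mutate_infinite_sites, simulate_structured
from .datamodel import LocusAlignment, SampleRecord, SampleTable, build_variant_table
from .io import StudyData

__all__ = ["TaxonSpec", "StudyScenario", "generate_study", "generate_study_files",
           "inject_selection"]

_BASES = np.array(list("ACGT"))


@dataclass
class TaxonSpec:
    name: str
    n_samples: int
    n_populations: int
    regions: list[str] = field(default_factory=list)  # per population, or empty


@dataclass
class StudyScenario:
    """Full specification of a synthetic study (defaults = paper-shaped)."""

    taxa: list[TaxonSpec] = field(default_factory=lambda: [
        TaxonSpec("Pmugo", 79, 8,
                  ["CE", "CE", "CE", "CP", "CP", "CP", "B", "B"]),
        TaxonSpec("Puliginosa", 24, 3),
        TaxonSpec("Puncinata", 50, 5),
    ])
    n_loci: int = 79
    mean_locus_length: int = 420
    sd_locus_length: int = 60
    # per-site theta: log-normal spanning the observed 0.0006-0.019 per-locus
    # range with mean pi near 0.004
    log_theta_mean: float = float(np.log(0.0035))
    log_theta_sd: float = 0.55
    # split topology ((Pmugo, Puliginosa), Puncinata), times in 4N units;
    # shallow splits keep shared polymorphism near 60% of polymorphic sites
    # and mean net divergence well below 0.001
    split_t1: float = 0.005
    split_t2: float = 0.01
    outgroup_t: float = 2.7
    m_within: float = 25.0  # island migration among populations of a taxon
    n_mtdna: int = 3
    mtdna_length: int = 500
    mtdna_theta: float = 0.001
    mtdna_m_within: float = 1.0
    mtdna_time_scale: float = 4.0  # smaller mt Ne -> deeper scaled splits
    indel_prob_per_locus: float = 0.2
    selected_loci: list[str] = field(default_factory=list)


def _sample_table(scenario: StudyScenario) -> tuple[SampleTable, dict, dict]:
    """Build sample records plus deme layout: deme index per sample and
    metadata about demes (taxon of each deme, migration groups)."""
    records = []
    deme_of_sample = []
    deme_taxon: list[int] = []
    deme_group: dict[int, int] = {}
    deme = 0
    for ti, tx in enumerate(scenario.taxa):
        base, rem = divmod(tx.n_samples, tx.n_populations)
        for pi in range(tx.n_populations):
            npop = base + (1 if pi < rem else 0)
            pop = f"{tx.name}_P{pi + 1:02d}"
            region = tx.regions[pi] if tx.regions else ""
            for si in range(npop):
                records.append(SampleRecord(
                    f"{pop}_{si + 1:02d}", tx.name, pop, region))
                deme_of_sample.append(deme)
            deme_taxon.append(ti)
            deme_group[deme] = ti
            deme += 1
    layout = dict(deme_taxon=deme_taxon, deme_group=deme_group, n_demes=deme)
    return SampleTable(records), np.array(deme_of_sample), layout


def _merge_events(scenario: StudyScenario, layout: dict, time_scale: float = 1.0
                  ) -> list[tuple[float, int, int]]:
    """Backward merges: taxa collapse into their first deme at the split time,
    then into the first taxon's deme; the outgroup deme joins last."""
    demes_by_taxon: dict[int, list[int]] = {}
    for d, ti in enumerate(layout["deme_taxon"]):
        demes_by_taxon.setdefault(ti, []).append(d)
    anchors = {ti: ds[0] for ti, ds in demes_by_taxon.items()}
    t1 = scenario.split_t1 * time_scale
    t2 = scenario.split_t2 * time_scale
    merges = []
    for ti, ds in demes_by_taxon.items():
        t_collapse = t1 if ti in (0, 1) else t2
        for d in ds[1:]:
            merges.append((t_collapse, anchors[ti], d))
    # taxon 1 joins taxon 0 at t1, any further taxa join at t2
    if 1 in anchors:
        merges.append((t1, anchors[0], anchors[1]))
    for ti in sorted(anchors):
        if ti >= 2:
            merges.append((t2, anchors[0], anchors[ti]))
    og_deme = layout["n_demes"]
    merges.append((scenario.outgroup_t, anchors[0], og_deme))
    return merges


def _locus_alignment(
    locus_id: str,
    sample_ids: list[str],
    deme_of_sample: np.ndarray,
    layout: dict,
    merges: list[tuple[float, int, int]],
    M: float,
    theta_site: float,
    L: int,
    rng: np.random.Generator,
    indel_prob: float,
) -> tuple[LocusAlignment, dict]:
    n = len(sample_ids)
    og_deme = layout["n_demes"]
    deme_of = list(deme_of_sample) + [og_deme]
    group_of = dict(layout["deme_group"])
    group_of[og_deme] = -1  # outgroup deme never migrates
    g = simulate_structured(
        deme_of, og_deme + 1, M, merges=merges, group_of=group_of, seed=rng
    )
    sim = mutate_infinite_sites(g, L=L, theta=theta_site * L, seed=rng)
    anc = rng.choice(_BASES, size=L)
    rows = np.tile(anc, (n + 1, 1))
    for k, pos in enumerate(sim.positions):
        derived = rng.choice([b for b in "ACGT" if b != anc[pos]])
        carriers = sim.matrix[:, k] == 1
        rows[carriers, pos] = derived
    # occasional indel polymorphism: short gap run in a random sample subset
    has_indel = False
    if rng.random() < indel_prob and L > 30:
        start = int(rng.integers(5, L - 10))
        width = int(rng.integers(2, 5))
        m = int(rng.integers(1, max(2, n // 3)))
        which = rng.choice(n, size=m, replace=False)
        for w in which:
            rows[w, start:start + width] = "-"
        has_indel = True
    seqs = ["".join(r) for r in rows[:n]]
    outgroup = "".join(rows[n])
    aln = LocusAlignment(locus_id, sample_ids, seqs, outgroup)
    truth = dict(theta_site=theta_site, L=L, S_simulated=int(sim.S),
                 tmrca=g.tmrca, has_indel=has_indel,
                 newick=None)
    return aln, truth


def generate_study(
    scenario: StudyScenario | None = None,
    seed: int | None = None,
    keep_genealogies: bool = False,
) -> tuple[StudyData, dict]:
    """Simulate a complete study; returns (StudyData, truth table).

    The truth table records every per-locus simulation parameter (theta, L,
    simulated S, TMRCA), the scenario and the master seed — enough to score
    any detection method without re-reading genealogies.
    """
    scenario = scenario or StudyScenario()
    rng = np.random.default_rng(seed)
    samples, deme_of_sample, layout = _sample_table(scenario)
    sample_ids = samples.sample_ids

    merges_nuc = _merge_events(scenario, layout, 1.0)
    merges_mt = _merge_events(scenario, layout, scenario.mtdna_time_scale)

    alignments = {}
    truth_loci = {}
    for li in range(scenario.n_loci):
        locus_id = f"L{li + 1:03d}"
        L = int(np.clip(rng.normal(scenario.mean_locus_length,
                                   scenario.sd_locus_length), 250, 650))
        theta_site = float(np.exp(rng.normal(scenario.log_theta_mean,
                                             scenario.log_theta_sd)))
        aln, tr = _locus_alignment(
            locus_id, sample_ids, deme_of_sample, layout, merges_nuc,
            scenario.m_within, theta_site, L, rng,
            scenario.indel_prob_per_locus,
        )
        alignments[locus_id] = aln
        truth_loci[locus_id] = tr

    mtdna_ids = []
    for mi in range(scenario.n_mtdna):
        locus_id = f"MT{mi + 1}"
        aln, tr = _locus_alignment(
            locus_id, sample_ids, deme_of_sample, layout, merges_mt,
            scenario.mtdna_m_within, scenario.mtdna_theta,
            scenario.mtdna_length, rng, 0.0,
        )
        alignments[locus_id] = aln
        truth_loci[locus_id] = tr
        mtdna_ids.append(locus_id)

    study = StudyData(samples, alignments, {}, mtdna_ids)
    truth = dict(
        seed=seed,
        scenario=dict(
            taxa=[(t.name, t.n_samples, t.n_populations) for t in scenario.taxa],
            n_loci=scenario.n_loci,
            split_t1=scenario.split_t1,
            split_t2=scenario.split_t2,
            outgroup_t=scenario.outgroup_t,
            m_within=scenario.m_within,
            log_theta_mean=scenario.log_theta_mean,
            log_theta_sd=scenario.log_theta_sd,
        ),
        loci=truth_loci,
        selected=list(scenario.selected_loci),
    )
    return study, truth


def generate_study_files(out_dir: str | Path, scenario: StudyScenario | None = None,
                         seed: int | None = None) -> Path:
    """Generate a study and write it to ``out_dir`` (FASTA + TSV + truth
    JSON); returns the config path for :func:`pinepop.io.load_study`."""
    from .io import write_study

    study, truth = generate_study(scenario, seed)
    cfg = write_study(study, out_dir)
    Path(out_dir, "truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n"
    )
    return cfg


def inject_selection(
    study: StudyData,
    loci: list[str],
    mechanism: str = "divergent",
    delta: float = 0.5,
    sweep_fraction: float = 0.9,
    target_taxon: str | None = None,
    seed: int | None = None,
) -> tuple[StudyData, dict]:
    """Add stylized selection signals to chosen loci, post-simulation.

    * ``divergent``: in the target taxon, shift each SNP's derived-allele
      frequency by ``delta`` (clipped to [0,1]) by reassigning carriers —
      raises per-SNP F_ST between the target taxon and the rest.
    * ``sweep_like``: in the target taxon, replace a fraction
      ``sweep_fraction`` of polymorphic columns by star-tree-like columns
      (mostly singletons with occasional near-fixed derived alleles) —
      skews the SFS toward singletons and high-frequency derived variants.

    Returns a modified copy of the study and a truth dict of injected flags.
    """
    if mechanism not in ("divergent", "sweep_like"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    missing = [l for l in loci if l not in study.alignments]
    if missing:
        raise KeyError(f"loci not in study: {missing}")
    rng = np.random.default_rng(seed)
    taxa = study.taxa()
    target_taxon = target_taxon or sorted(taxa)[0]
    target = set(taxa[target_taxon])
    truth = dict(mechanism=mechanism, delta=delta, sweep_fraction=sweep_fraction,
                 target_taxon=target_taxon, loci=list(loci), sites={})

    new_alignments = dict(study.alignments)
    for locus in loci:
        aln = study.alignments[locus]
        mat = aln.matrix.copy()
        rows_t = [i for i, s in enumerate(aln.sample_ids) if s in target]
        vt = build_variant_table(aln, include_indels=False)
        touched = []
        for i, site in enumerate(vt.sites.itertuples(index=False)):
            j = site.position
            col = mat[rows_t, j]
            called = [c for c in col if c in "ACGT"]
            if not called:
                continue
            alleles = sorted(set(called))
            if len(alleles) == 1:
                base_minor = next(
                    (a for a in site.alleles.split(",") if a != alleles[0]), None)
                if base_minor is None:
                    continue
                minor = base_minor
                major = alleles[0]
            else:
                cnt = {a: called.count(a) for a in alleles}
                minor = min(alleles, key=lambda a: (cnt[a], a))
                major = max(alleles, key=lambda a: (cnt[a], a))
            nt = len(rows_t)
            if mechanism == "divergent":
                k_cur = col.tolist().count(minor)
                p_new = min(1.0, k_cur / nt + delta)
                k_new = int(round(p_new * nt))
                if k_new == k_cur:
                    continue
                newcol = col.copy()
                if k_new > k_cur:
                    pool = np.where(newcol != minor)[0]
                    add = rng.choice(pool, size=k_new - k_cur, replace=False)
                    newcol[add] = minor
                else:
                    pool = np.where(newcol == minor)[0]
                    drop = rng.choice(pool, size=k_cur - k_new, replace=False)
                    newcol[drop] = major
                mat[rows_t, j] = newcol
                touched.append(int(j))
            else:
                if rng.random() < sweep_fraction:
                    newcol = np.full(nt, major, dtype="U1")
                    if rng.random() < 0.1:
                        # near-fixed derived allele
                        spare = int(rng.integers(nt))
                        newcol[:] = minor
                        newcol[spare] = major
                    else:
                        newcol[int(rng.integers(nt))] = minor
                    mat[rows_t, j] = newcol
                    touched.append(int(j))
        truth["sites"][locus] = touched
        new_alignments[locus] = LocusAlignment(
            locus,
            aln.sample_ids,
            ["".join(r) for r in mat],
            None if aln.outgroup is None else "".join(aln.outgroup),
        )
    out = StudyData(study.samples, new_alignments, study.annotations,
                    list(study.mtdna_ids), study.coverage,
                    list(study.low_coverage_loci))
    return out, truth
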