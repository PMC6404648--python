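"""End-to-end study analysis.

Convenience layer that runs the whole analysis on a loaded
:class:`~pinepop.io.StudyData`: per-group diversity summaries, multilocus
theta posterior, divergence and sharing, multilocus and compound neutrality
tests, HKA, AMOVA / pairwise F_ST / S_nn, the two outlier scans, FDR control
and the final evidence matrix.

Two presets are wired: ``paper`` uses the study's published simulation and
permutation settings (1000 permutations, 10,000 compound-test simulations,
20,000 outlier-envelope replicates, 100,000 theta-posterior samples);
``fast`` scales replicate counts down for desk-scale runs while leaving
every model choice unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import diversity as dv
from .datamodel import build_variant_table, extract_haplotypes, polarize_variants
from .differentiation import (
    amova,
    pairwise_difference_matrix,
    pairwise_fst,
    per_site_fst,
    snn,
)
from .divergence import (
    concatenated_snp_matrix,
    haplotype_sharing,
    net_divergence,
    polymorphism_sharing,
)
from .io import StudyData
from .neutrality import (
    CompoundTester,
    NullBank,
    _k_mean_from_vt,
    fay_wu_h_value,
    hka_test,
    multilocus_tajima,
    tajima_d_value,
)
from .outliers import bayescan_like, fdist_scan, storey_qvalues
from .synthesis import build_evidence_matrix, candidate_genes

__all__ = ["PipelineSettings", "PRESETS", "diversity_table", "divergence_table",
           "snp_count_table", "analyze_study"]


@dataclass
class PipelineSettings:
    permutations: int = 1000
    compound_reps: int = 10000
    compound_alpha: float = 0.05
    theta_samples: int = 100_000
    theta_burn_in: int = 5000
    fdist_reps: int = 20000
    fdist_demes: int = 100
    run_bayescan: bool = False
    bayescan_burn_in: int = 50000
    bayescan_samples: int = 5000
    bayescan_thin: int = 10
    bayescan_pilots: int = 20
    bayescan_pilot_length: int = 5000
    alpha_fst: float = 0.01
    alpha_compound: float = 0.05
    seed: int = 0


PRESETS = {
    "paper": PipelineSettings(),
    "fast": PipelineSettings(
        permutations=300, compound_reps=1500, theta_samples=20000,
        theta_burn_in=1000, fdist_reps=4000,
        bayescan_burn_in=3000, bayescan_samples=1500, bayescan_thin=2,
        bayescan_pilots=4, bayescan_pilot_length=500,
    ),
}


def _group_map(study: StudyData) -> dict[str, list[str]]:
    """Taxa plus regional groups (region label prefixed by taxon)."""
    groups = dict(study.taxa())
    for r in study.samples.records:
        if r.region:
            groups.setdefault(f"{r.taxon}:{r.region}", []).append(r.sample_id)
    return groups


def diversity_table(
    study: StudyData,
    settings: PipelineSettings | None = None,
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Multilocus diversity summary per group (Table-1 shape): n, total
    length, S, singletons, pi, Watterson-theta posterior median and 95% CI,
    multilocus Tajima's D with coalescent p, mean haplotype number and
    haplotype diversity."""
    settings = settings or PRESETS["fast"]
    groups = groups or _group_map(study)
    bank = NullBank(settings.seed)
    rows = []
    for gname in sorted(groups):
        samples = groups[gname]
        S_list, n_list, L_list = [], [], []
        pis, hds, nhaps = [], [], []
        d_loci = []
        for lid in study.nuclear_ids:
            aln = study.alignments[lid]
            present = [s for s in samples if s in set(aln.sample_ids)]
            if len(present) < 2:
                continue
            vt = build_variant_table(aln, present)
            S_list.append(vt.S_snp)
            n_list.append(vt.n_samples)
            L_list.append(aln.length)
            pis.append(dv.nucleotide_diversity(vt, aln.length))
            hs = extract_haplotypes(aln, present)
            nhaps.append(hs.N)
            if hs.n >= 2:
                hds.append(dv.haplotype_diversity(hs)[0])
            d_loci.append((vt.n_samples, vt.S_snp, _k_mean_from_vt(vt)))
        post = dv.multilocus_theta_posterior(
            np.array(S_list), np.array(n_list), np.array(L_list),
            burn_in=settings.theta_burn_in, samples=settings.theta_samples,
            seed=settings.seed,
        )
        mlt = multilocus_tajima(d_loci, reps=settings.permutations, bank=bank)
        sg = 0
        for lid in study.nuclear_ids:
            aln = study.alignments[lid]
            present = [s for s in samples if s in set(aln.sample_ids)]
            if len(present) >= 2:
                sg += build_variant_table(aln, present).S_singleton
        rows.append(dict(
            group=gname, n=len(samples), n_loci=len(S_list),
            L_total=int(np.sum(L_list)), S=int(np.sum(S_list)), S_g=sg,
            pi_total=float(np.mean(pis)),
            theta_median=post.median, theta_ci_low=post.ci_low,
            theta_ci_high=post.ci_high,
            tajima_D=mlt.statistic, tajima_p=mlt.p_one_sided,
            N_hap_mean=float(np.mean(nhaps)), Hd_mean=float(np.mean(hds)),
        ))
    return pd.DataFrame(rows)


def divergence_table(study: StudyData) -> pd.DataFrame:
    """Pairwise-taxa multilocus divergence: mean d_xy and net d_a, shared /
    exclusive / fixed site totals, haplotype sharing, plus the mean net
    divergence of each taxon from the outgroup."""
    taxa = study.taxa()
    names = sorted(taxa)
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            g1, g2 = taxa[names[a]], taxa[names[b]]
            dxy_l, da_l = [], []
            tot = dict(shared=0, exclusive_1=0, exclusive_2=0, fixed=0)
            hap_shared, hap_u1, hap_u2 = 0, 0, 0
            for lid in study.nuclear_ids:
                aln = study.alignments[lid]
                dxy, da = net_divergence(aln, g1, g2)
                dxy_l.append(dxy)
                da_l.append(da)
                c = polymorphism_sharing(aln, g1, g2)
                for k in tot:
                    tot[k] += c[k]
                hsh = haplotype_sharing(
                    extract_haplotypes(aln, g1), extract_haplotypes(aln, g2))
                hap_shared += hsh["shared"]
                hap_u1 += hsh["unique_1"]
                hap_u2 += hsh["unique_2"]
            denom = tot["shared"] + tot["exclusive_1"] + tot["exclusive_2"]
            rows.append(dict(
                taxon_1=names[a], taxon_2=names[b],
                dxy_mean=float(np.mean(dxy_l)), da_mean=float(np.mean(da_l)),
                **tot,
                shared_fraction=tot["shared"] / denom if denom else np.nan,
                hap_shared=hap_shared, hap_unique_1=hap_u1, hap_unique_2=hap_u2,
            ))
    out = pd.DataFrame(rows)
    og = []
    for name in names:
        das = []
        for lid in study.nuclear_ids:
            aln = study.alignments[lid]
            if aln.outgroup is None:
                continue
            das.append(net_divergence(aln, taxa[name], None)[1])
        og.append(dict(taxon=name,
                       outgroup_net_divergence=float(np.mean(das)) if das else np.nan))
    out.attrs["outgroup"] = pd.DataFrame(og)
    return out


def snp_count_table(
    study: StudyData,
    groups: dict[str, list[str]],
    loci: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP minor-allele counts and sample sizes per group across loci.

    Multiallelic SNPs are reduced to major-vs-rest (flagged).  Columns:
    locus, position, maf plus count_<g> / size_<g> per group.
    """
    names = sorted(groups)
    rows = []
    for lid in loci or study.nuclear_ids:
        aln = study.alignments[lid]
        all_samples = [s for g in names for s in groups[g]
                       if s in set(aln.sample_ids)]
        if len(all_samples) < 2:
            continue
        vt = build_variant_table(aln, all_samples, include_indels=False)
        ids = vt.sample_ids
        gidx = {g: [i for i, s in enumerate(ids) if s in set(groups[g])]
                for g in names}
        for i, site in enumerate(vt.sites.itertuples(index=False)):
            geno = vt.genotypes[i]
            alleles = site.alleles.split(",")
            row = dict(locus=lid, position=site.position, maf=site.maf,
                       multiallelic=len(alleles) > 2)
            for g in names:
                sub = geno[gidx[g]]
                called = sub[sub >= 0]
                row[f"count_{g}"] = int(np.sum(called != 0))  # non-major
                row[f"size_{g}"] = int(len(called))
            rows.append(row)
    return pd.DataFrame(rows)


def _locus_distance_tables(study: StudyData, samples: list[str]):
    """Per-locus pairwise-difference matrices restricted to ``samples``."""
    out = {}
    for lid in study.nuclear_ids:
        aln = study.alignments[lid]
        present = [s for s in samples if s in set(aln.sample_ids)]
        if len(present) < 4:
            continue
        mat = aln.rows(present)
        out[lid] = (pairwise_difference_matrix(mat), aln.subset_ids(present))
    return out


def analyze_study(
    study: StudyData,
    settings: PipelineSettings | str = "fast",
) -> dict:
    """Run the full analysis; returns a dict of result tables.

    Keys: diversity, divergence, amova, fst_taxa, fst_taxa_p, per-locus
    evidence inputs (fst_between, fst_within, snn_within, diverged_snps,
    outlier_snps, compound), fdr, evidence (EvidenceMatrix), candidates,
    shared_across_taxa, and optionally bayescan.
    """
    if isinstance(settings, str):
        settings = PRESETS[settings]
    rng = np.random.default_rng(settings.seed)
    taxa = study.taxa()
    names = sorted(taxa)
    pops = study.populations()
    bank = NullBank(settings.seed)
    results: dict = {}

    results["diversity"] = diversity_table(study, settings)
    results["divergence"] = divergence_table(study)

    # --- genome-wide AMOVA and taxa-level F_ST on concatenated SNPs ---------
    all_samples = study.samples.sample_ids
    snp_mat = concatenated_snp_matrix(
        [study.alignments[l] for l in study.nuclear_ids], all_samples)
    D_all = pairwise_difference_matrix(snp_mat)
    pop_of = np.array([study.samples[s].population for s in all_samples])
    taxon_of = np.array([study.samples[s].taxon for s in all_samples])
    results["amova"] = amova(D_all, pop_of, taxon_of,
                             permutations=settings.permutations, seed=rng)
    fst_m, fst_p = pairwise_fst(D_all, taxon_of,
                                permutations=settings.permutations, seed=rng)
    results["fst_taxa"] = fst_m
    results["fst_taxa_p"] = fst_p

    # --- per-locus differentiation (evidence codes 1-3) ----------------------
    fst_between_rows, fst_within_rows, snn_rows = [], [], []
    for lid in study.nuclear_ids:
        aln = study.alignments[lid]
        mat = aln.rows()
        D = pairwise_difference_matrix(mat)
        ids = aln.sample_ids
        tx = np.array([study.samples[s].taxon for s in ids])
        pp = np.array([study.samples[s].population for s in ids])
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                ii = np.where((tx == names[a]) | (tx == names[b]))[0]
                if len(np.unique(tx[ii])) < 2:
                    continue
                sub = D[np.ix_(ii, ii)]
                if sub.max() == 0:
                    continue
                res = amova(sub, tx[ii], permutations=settings.permutations,
                            seed=rng)
                for t_this, t_other in ((names[a], names[b]),
                                        (names[b], names[a])):
                    fst_between_rows.append(dict(
                        gene=lid, taxon=t_this, other_taxon=t_other,
                        fst=res.phi["phi_st"], p=res.p_values["phi_st"]))
        for t in names:
            ii = np.where(tx == t)[0]
            if len(np.unique(pp[ii])) < 2:
                continue
            sub = D[np.ix_(ii, ii)]
            if sub.max() == 0:
                continue
            res = amova(sub, pp[ii], permutations=settings.permutations,
                        seed=rng)
            fst_within_rows.append(dict(gene=lid, taxon=t,
                                        fst=res.phi["phi_st"],
                                        p=res.p_values["phi_st"]))
            counts = pd.Series(pp[ii]).value_counts()
            if counts.min() >= 2:
                sr = snn(sub, pp[ii], permutations=settings.permutations,
                         seed=rng)
                snn_rows.append(dict(gene=lid, taxon=t,
                                     grouping="populations",
                                     snn=sr.snn, p=sr.p_value))
    results["fst_between"] = pd.DataFrame(fst_between_rows)
    results["fst_within"] = pd.DataFrame(fst_within_rows)
    results["snn_within"] = pd.DataFrame(snn_rows)

    # FDR summary over the per-locus F_ST permutation p-values
    all_p = pd.concat([results["fst_between"]["p"],
                       results["fst_within"]["p"]], ignore_index=True)
    results["fdr"] = storey_qvalues(all_p.to_numpy(), lam=0.15)

    # --- compound neutrality tests (code 6) ----------------------------------
    tester = CompoundTester(bank, reps=settings.compound_reps,
                            alpha=settings.compound_alpha)
    compound_rows = []
    for t in names:
        for lid in study.nuclear_ids:
            aln = study.alignments[lid]
            present = [s for s in taxa[t] if s in set(aln.sample_ids)]
            if len(present) < 4:
                continue
            vt = build_variant_table(aln, present)
            if vt.S_snp < 1:
                continue
            if aln.outgroup is not None:
                vt = polarize_variants(vt, aln.outgroup)
            n = vt.n_samples
            d_obs = tajima_d_value(vt.S_snp, n, _k_mean_from_vt(vt))
            xi = vt.snp_only().sites["derived_count"].to_numpy()
            xi = xi[xi >= 1]
            if len(xi) == 0:
                continue
            h_obs, _ = fay_wu_h_value(xi, n)
            hs = extract_haplotypes(aln, present)
            f_obs = hs.homozygosity
            cr = tester.test_locus(d_obs, h_obs, f_obs, n, vt.S_snp)
            compound_rows.append(dict(
                gene=lid, taxon=t, D=d_obs, H=h_obs, F=f_obs,
                hew=cr.reject_hew, dhew=cr.reject_dhew,
                **{k: v for k, v in cr.p_components.items()}))
    results["compound"] = pd.DataFrame(compound_rows)

    # --- HKA per taxon --------------------------------------------------------
    hka = {}
    for t in names:
        S_l, D_l, n_l = [], [], []
        for lid in study.nuclear_ids:
            aln = study.alignments[lid]
            if aln.outgroup is None:
                continue
            present = [s for s in taxa[t] if s in set(aln.sample_ids)]
            if len(present) < 2:
                continue
            vt = build_variant_table(aln, present)
            dxy, _ = net_divergence(aln, present, None)
            S_l.append(vt.S_snp)
            D_l.append(dxy * aln.length)
            n_l.append(len(present))
        if len(S_l) >= 2:
            hka[t] = hka_test(np.array(S_l), np.array(D_l), np.array(n_l))
    results["hka"] = hka

    # --- outlier scans (codes 4 and 5) ----------------------------------------
    snp_taxa = snp_count_table(study, taxa)
    diverged_rows, outlier_rows = [], []
    if len(snp_taxa):
        counts = snp_taxa[[f"count_{g}" for g in names]].to_numpy(float)
        sizes = snp_taxa[[f"size_{g}" for g in names]].to_numpy(float)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                cc = counts[:, [a, b]]
                ss = sizes[:, [a, b]]
                fst, he = per_site_fst(cc, ss)
                ok = ~np.isnan(fst)
                if ok.sum() < 20 or np.nanmean(fst) <= 0:
                    continue
                scan = fdist_scan(
                    fst, he, [int(ss[:, 0].max()), int(ss[:, 1].max())],
                    demes=settings.fdist_demes, reps=settings.fdist_reps,
                    seed=int(rng.integers(2**31 - 1)),
                    counts_obs=cc, sizes_obs=ss)
                for k in np.where(scan.table["flag99"].to_numpy())[0]:
                    for t_this, t_other in ((names[a], names[b]),
                                            (names[b], names[a])):
                        diverged_rows.append(dict(
                            gene=snp_taxa["locus"].iloc[k], taxon=t_this,
                            other_taxon=t_other,
                            position=int(snp_taxa["position"].iloc[k]),
                            flag99=True))
    for t in names:
        pop_groups = {p: pops[p] for p in pops if p.startswith(t)}
        if len(pop_groups) < 2:
            continue
        snp_pops = snp_count_table(study, pop_groups)
        if not len(snp_pops):
            continue
        pnames = sorted(pop_groups)
        cc = snp_pops[[f"count_{g}" for g in pnames]].to_numpy(float)
        ss = snp_pops[[f"size_{g}" for g in pnames]].to_numpy(float)
        fst, he = per_site_fst(cc, ss)
        if np.sum(~np.isnan(fst)) < 20 or np.nanmean(fst) <= 0:
            continue
        scan = fdist_scan(
            fst, he, [int(s) for s in ss.max(axis=0)],
            demes=settings.fdist_demes, reps=settings.fdist_reps,
            seed=int(rng.integers(2**31 - 1)),
            counts_obs=cc, sizes_obs=ss)
        flagged = scan.table["flag95"].to_numpy()
        for k in np.where(flagged)[0]:
            outlier_rows.append(dict(gene=snp_pops["locus"].iloc[k], taxon=t,
                                     position=int(snp_pops["position"].iloc[k]),
                                     flag=True))
        if settings.run_bayescan:
            bs = bayescan_like(
                cc, ss,
                burn_in=settings.bayescan_burn_in,
                samples=settings.bayescan_samples,
                thin=settings.bayescan_thin,
                pilot_runs=settings.bayescan_pilots,
                pilot_length=settings.bayescan_pilot_length,
                seed=int(rng.integers(2**31 - 1)))
            results.setdefault("bayescan", {})[t] = bs

    results["diverged_snps"] = pd.DataFrame(
        diverged_rows, columns=["gene", "taxon", "other_taxon", "position",
                                "flag99"])
    results["outlier_snps"] = pd.DataFrame(
        outlier_rows, columns=["gene", "taxon", "position", "flag"])

    # --- evidence matrix ------------------------------------------------------
    matrix = build_evidence_matrix(
        fst_between=results["fst_between"] if len(fst_between_rows) else None,
        fst_within=results["fst_within"] if len(fst_within_rows) else None,
        snn_within=results["snn_within"] if len(snn_rows) else None,
        diverged_snps=results["diverged_snps"] if diverged_rows else None,
        outlier_snps=results["outlier_snps"] if outlier_rows else None,
        compound=results["compound"] if compound_rows else None,
        alpha_fst=settings.alpha_fst,
        alpha_compound=settings.alpha_compound,
    )
    results["evidence"] = matrix
    cands, shared = candidate_genes(matrix)
    results["candidates"] = cands
    results["shared_across_taxa"] = shared
    return results
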