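"""Evidence-matrix synthesis: integrate every test's output per gene x taxon
and apply the candidate-gene rule.

Evidence codes (one flag set per gene x taxon):

1. significant F_ST at interspecies level (annotated with the other taxa)
2. significant F_ST among populations within the taxon
3. significant S_nn within the taxon (annotated with the grouping)
4. highly diverged SNPs at interspecific level (99% envelope outliers,
   annotated with the other taxa)
5. outlier SNPs within the taxon
6. significant HEW and/or DHEW compound tests (annotated with which)

A candidate gene (within one taxon) carries flag 6 AND (1 or 4) AND
(2, 3 or 5) — deviation from neutrality plus between-taxon divergence plus a
within-taxon selection signature.  Cross-taxon sharing of any signal is
reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["EvidenceMatrix", "build_evidence_matrix", "candidate_genes"]


@dataclass
class EvidenceMatrix:
    """flags[(gene, taxon)] = set of codes; annotations[(gene, taxon)][code]
    = list of annotation strings (other taxa, groupings, test names)."""

    flags: dict[tuple[str, str], set[int]] = field(default_factory=dict)
    annotations: dict[tuple[str, str], dict[int, list[str]]] = field(
        default_factory=dict
    )
    provenance: dict[tuple[str, str], dict[int, list[str]]] = field(
        default_factory=dict
    )

    def add(self, gene: str, taxon: str, code: int, annotation: str | None,
            source: str) -> None:
        if code not in range(1, 7):
            raise ValueError(f"evidence code {code} outside 1..6")
        key = (gene, taxon)
        self.flags.setdefault(key, set()).add(code)
        if annotation:
            ann = self.annotations.setdefault(key, {}).setdefault(code, [])
            if annotation not in ann:
                ann.append(annotation)
        self.provenance.setdefault(key, {}).setdefault(code, []).append(source)

    def flag_string(self, gene: str, taxon: str) -> str:
        codes = sorted(self.flags.get((gene, taxon), set()))
        parts = []
        for c in codes:
            ann = self.annotations.get((gene, taxon), {}).get(c)
            parts.append(f"{c}^{','.join(ann)}^" if ann else str(c))
        return ",".join(parts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(gene=g, taxon=t, flags=",".join(map(str, sorted(f))),
                 annotated=self.flag_string(g, t))
            for (g, t), f in sorted(self.flags.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "taxon", "flags", "annotated"])


def build_evidence_matrix(
    fst_between: pd.DataFrame | None = None,
    fst_within: pd.DataFrame | None = None,
    snn_within: pd.DataFrame | None = None,
    diverged_snps: pd.DataFrame | None = None,
    outlier_snps: pd.DataFrame | None = None,
    compound: pd.DataFrame | None = None,
    alpha_fst: float = 0.01,
    alpha_compound: float = 0.05,
) -> EvidenceMatrix:
    """Assemble the per-gene evidence matrix from tidy result tables.

    Expected columns (extra columns ignored; any table may be None, its codes
    are then simply absent):

    * ``fst_between``: gene, taxon, other_taxon, p        -> code 1 (p < alpha_fst)
    * ``fst_within``:  gene, taxon, p                     -> code 2 (p < alpha_fst)
    * ``snn_within``:  gene, taxon, grouping, p           -> code 3 (p < alpha_fst)
    * ``diverged_snps``: gene, taxon, other_taxon, flag99 -> code 4 (any flagged SNP)
    * ``outlier_snps``:  gene, taxon, flag                -> code 5 (any flagged SNP)
    * ``compound``: gene, taxon, hew, dhew (booleans at alpha_compound)
                                                          -> code 6 (annotated HEW/DHEW)

    The assembly is deterministic: identical inputs give identical matrices.
    """
    m = EvidenceMatrix()
    if fst_between is not None:
        for r in fst_between.itertuples(index=False):
            if r.p < alpha_fst:
                m.add(r.gene, r.taxon, 1, str(r.other_taxon),
                      f"fst_between:{r.gene}:{r.taxon}:{r.other_taxon}")
    if fst_within is not None:
        for r in fst_within.itertuples(index=False):
            if r.p < alpha_fst:
                m.add(r.gene, r.taxon, 2, None, f"fst_within:{r.gene}:{r.taxon}")
    if snn_within is not None:
        for r in snn_within.itertuples(index=False):
            if r.p < alpha_fst:
                m.add(r.gene, r.taxon, 3, str(getattr(r, "grouping", "") or ""),
                      f"snn:{r.gene}:{r.taxon}")
    if diverged_snps is not None:
        for r in diverged_snps.itertuples(index=False):
            if r.flag99:
                m.add(r.gene, r.taxon, 4, str(r.other_taxon),
                      f"diverged_snp:{r.gene}:{r.taxon}:{r.other_taxon}")
    if outlier_snps is not None:
        for r in outlier_snps.itertuples(index=False):
            if r.flag:
                m.add(r.gene, r.taxon, 5, None, f"outlier_snp:{r.gene}:{r.taxon}")
    if compound is not None:
        for r in compound.itertuples(index=False):
            tests = [name for name, hit in (("HEW", r.hew), ("DHEW", r.dhew)) if hit]
            for tname in tests:
                m.add(r.gene, r.taxon, 6, tname, f"compound:{r.gene}:{r.taxon}")
    return m


def candidate_genes(matrix: EvidenceMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the candidate rule and summarize cross-taxon signal sharing.

    Candidates: gene x taxon with 6 AND (1 or 4) AND (2, 3 or 5), ordered by
    flag count (descending) then gene id (ascending).  The second frame lists
    genes carrying any selection signal in more than one taxon.
    """
    rows = []
    for (gene, taxon), flags in matrix.flags.items():
        if 6 in flags and (flags & {1, 4}) and (flags & {2, 3, 5}):
            rows.append(dict(gene=gene, taxon=taxon,
                             n_flags=len(flags),
                             flags=",".join(map(str, sorted(flags)))))
    rows.sort(key=lambda r: (-r["n_flags"], r["gene"], r["taxon"]))
    cands = pd.DataFrame(rows, columns=["gene", "taxon", "n_flags", "flags"])

    by_gene: dict[str, list[str]] = {}
    for (gene, taxon), flags in sorted(matrix.flags.items()):
        if flags:
            by_gene.setdefault(gene, []).append(taxon)
    shared = pd.DataFrame(
        [dict(gene=g, taxa=",".join(ts), n_taxa=len(ts))
         for g, ts in sorted(by_gene.items()) if len(ts) > 1],
        columns=["gene", "taxa", "n_taxa"],
    )
    return cands, shared
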