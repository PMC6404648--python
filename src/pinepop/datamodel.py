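"""Core data containers: sample metadata, per-locus alignments, variant tables,
haplotype sets and site-class annotation.

Alignments hold haploid sequences (one row per megagametophyte-derived sample)
over the characters ``A C G T - N``; IUPAC ambiguity codes are converted to
``N`` on construction.  All coordinates are 0-based half-open internally;
report writers convert to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_CHARS = frozenset("ACGT-N")
_BASES = frozenset("ACGT")

__all__ = [
    "SampleRecord",
    "SampleTable",
    "LocusAlignment",
    "SiteAnnotation",
    "VariantTable",
    "HaplotypeSet",
    "build_variant_table",
    "polarize_variants",
    "extract_haplotypes",
]


@dataclass(frozen=True)
class SampleRecord:
    """One haploid sample: taxon, population and (optionally) regional group."""

    sample_id: str
    taxon: str
    population: str
    region: str = ""


class SampleTable:
    """Collection of :class:`SampleRecord` with unique ids and lookups by group."""

    def __init__(self, records: Iterable[SampleRecord]):
        self.records = list(records)
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        self._by_id = {r.sample_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def group(self, level: str) -> dict[str, list[str]]:
        """Map group label -> sample ids at ``level`` in {taxon, population, region}."""
        if level not in ("taxon", "population", "region"):
            raise ValueError(f"unknown grouping level {level!r}")
        out: dict[str, list[str]] = {}
        for r in self.records:
            key = getattr(r, level)
            if key == "":
                continue
            out.setdefault(key, []).append(r.sample_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.taxon, r.population, r.region) for r in self.records],
            columns=["sample_id", "taxon", "population", "region"],
        )


def _clean_sequence(seq: str) -> str:
    """Uppercase; IUPAC ambiguity codes and anything unrecognised become N."""
    s = seq.upper()
    return "".join(c if c in VALID_CHARS else "N" for c in s)


class LocusAlignment:
    """Haploid multiple alignment for one locus.

    Parameters
    ----------
    locus_id : str
    sample_ids : sequence of str
        Row labels, same order as ``sequences``.
    sequences : sequence of str
        Aligned sequences (equal length) over A/C/G/T/-/N.
    outgroup_seq : str, optional
        Outgroup sequence aligned to the same columns.
    """

    def __init__(
        self,
        locus_id: str,
        sample_ids: Sequence[str],
        sequences: Sequence[str],
        outgroup_seq: str | None = None,
    ):
        if len(sample_ids) != len(sequences):
            raise ValueError("sample_ids and sequences length mismatch")
        if len(sequences) < 2:
            raise ValueError(f"locus {locus_id}: need >= 2 samples")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError(f"locus {locus_id}: unequal aligned lengths {lengths}")
        (L,) = lengths
        if L == 0:
            raise ValueError(f"locus {locus_id}: zero-length alignment")
        self.locus_id = locus_id
        self.sample_ids = list(sample_ids)
        self.matrix = np.array(
            [list(_clean_sequence(s)) for s in sequences], dtype="U1"
        )
        if outgroup_seq is not None:
            if len(outgroup_seq) != L:
                raise ValueError(f"locus {locus_id}: outgroup length != {L}")
            self.outgroup = np.array(list(_clean_sequence(outgroup_seq)), dtype="U1")
        else:
            self.outgroup = None
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def rows(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Character matrix restricted to ``subset`` (alignment order preserved)."""
        if subset is None:
            return self.matrix
        missing = [s for s in subset if s not in self._index]
        if missing:
            raise KeyError(f"locus {self.locus_id}: samples not in alignment: {missing}")
        idx = sorted(self._index[s] for s in subset)
        return self.matrix[idx]

    def subset_ids(self, subset: Sequence[str] | None = None) -> list[str]:
        if subset is None:
            return list(self.sample_ids)
        idx = sorted(self._index[s] for s in subset)
        return [self.sample_ids[i] for i in idx]


@dataclass
class SiteAnnotation:
    """Coding intervals (0-based half-open, with frame) for one locus."""

    locus_id: str
    coding_intervals: list[tuple[int, int, int]] = field(default_factory=list)

    def validate(self, L_total: int) -> None:
        prev_end = -1
        for start, end, frame in sorted(self.coding_intervals):
            if not (0 <= start < end <= L_total):
                raise ValueError(
                    f"{self.locus_id}: interval ({start},{end}) outside [0,{L_total})"
                )
            if frame not in (0, 1, 2):
                raise ValueError(f"{self.locus_id}: frame {frame} not in {{0,1,2}}")
            if start < prev_end:
                raise ValueError(f"{self.locus_id}: overlapping coding intervals")
            prev_end = end

    def site_class(self, L_total: int) -> np.ndarray:
        """Per-column class array: True where coding."""
        self.validate(L_total)
        coding = np.zeros(L_total, dtype=bool)
        for start, end, _ in self.coding_intervals:
            coding[start:end] = True
        return coding


@dataclass
class VariantTable:
    """Polymorphic sites for one locus restricted to a sample subset.

    ``sites`` columns: position (0-based; for indels the first gap column),
    type ('SNP'|'indel'), alleles (comma-joined; indel alleles are presence/
    absence codes), counts (comma-joined, same order as alleles), n_called,
    ancestral (allele string or ''), derived_count (ξ_i, -1 if unpolarized),
    is_singleton, is_informative, maf, end (half-open end column; position+1
    for SNPs).
    """

    locus_id: str
    sample_ids: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray  # (S_rows, n) allele index per sample, -1 = missing
    L_total: int

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def S(self) -> int:
        """Total polymorphic sites (SNPs + indel events)."""
        return len(self.sites)

    @property
    def S_snp(self) -> int:
        return int((self.sites["type"] == "SNP").sum())

    @property
    def S_singleton(self) -> int:
        return int(self.sites["is_singleton"].sum())

    def snp_only(self) -> "VariantTable":
        mask = (self.sites["type"] == "SNP").to_numpy()
        return VariantTable(
            self.locus_id,
            self.sample_ids,
            self.sites.loc[mask].reset_index(drop=True),
            self.genotypes[mask],
            self.L_total,
        )

    def allele_lists(self) -> list[list[str]]:
        return [a.split(",") for a in self.sites["alleles"]]


def _site_alleles(col: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Distinct called bases at a SNP column and per-sample allele indices."""
    called = [c for c in col if c in _BASES]
    alleles = sorted(set(called), key=lambda b: (-called.count(b), b))
    amap = {a: i for i, a in enumerate(alleles)}
    geno = np.array([amap.get(c, -1) for c in col], dtype=np.int16)
    return alleles, geno


def build_variant_table(
    aln: LocusAlignment,
    subset: Sequence[str] | None = None,
    include_indels: bool = True,
) -> VariantTable:
    """Scan an alignment for polymorphic sites within a sample subset.

    SNP rows are alignment columns with >=2 distinct called bases (gaps and N
    treated as missing).  A maximal run of adjacent gap columns sharing the
    same presence/absence pattern across samples is collapsed into a single
    indel polymorphism (coded presence=0 / absence=1), counted in the
    polymorphic-site total but excluded from per-site statistics downstream.
    """
    mat = aln.rows(subset)
    ids = aln.subset_ids(subset)
    n = mat.shape[0]
    if n < 2:
        raise ValueError(f"locus {aln.locus_id}: need >= 2 samples in subset")

    rows = []
    genos = []
    # SNPs: vectorized scan for columns with >= 2 distinct called bases
    base_codes = np.full(mat.shape, -1, dtype=np.int8)
    for code, b in enumerate("ACGT"):
        base_codes[mat == b] = code
    counts4 = np.stack([(base_codes == c).sum(axis=0) for c in range(4)])
    snp_cols = np.where((counts4 > 0).sum(axis=0) >= 2)[0]
    for j in snp_cols:
        col = mat[:, j]
        alleles, geno = _site_alleles(col)
        counts = np.bincount(geno[geno >= 0], minlength=len(alleles))
        n_called = int(counts.sum())
        sorted_counts = np.sort(counts)[::-1]
        minor = int(n_called - sorted_counts[0])
        biallelic_minor = int(sorted_counts[1]) if len(alleles) >= 2 else 0
        rows.append(
            dict(
                position=j,
                end=j + 1,
                type="SNP",
                alleles=",".join(alleles),
                counts=",".join(map(str, counts)),
                n_called=n_called,
                ancestral="",
                derived_count=-1,
                is_singleton=biallelic_minor == 1 and len(alleles) == 2,
                is_informative=len(alleles) == 2 and biallelic_minor >= 2,
                maf=minor / n_called,
            )
        )
        genos.append(geno)

    # Indels: maximal gap-column runs with identical presence/absence pattern
    if include_indels:
        gap = mat == "-"
        any_gap = gap.any(axis=0)
        j = 0
        while j < mat.shape[1]:
            if not any_gap[j]:
                j += 1
                continue
            pattern = gap[:, j]
            k = j + 1
            while k < mat.shape[1] and any_gap[k] and np.array_equal(gap[:, k], pattern):
                k += 1
            # missing if N anywhere in the run
            missing = (mat[:, j:k] == "N").any(axis=1)
            geno = np.where(missing, -1, pattern.astype(np.int16))
            called = geno[geno >= 0]
            if len(called) >= 2 and 0 < called.sum() < len(called):
                counts = np.bincount(called, minlength=2)
                n_called = int(counts.sum())
                minor = int(counts.min())
                rows.append(
                    dict(
                        position=j,
                        end=k,
                        type="indel",
                        alleles="present,absent",
                        counts=",".join(map(str, counts)),
                        n_called=n_called,
                        ancestral="",
                        derived_count=-1,
                        is_singleton=minor == 1,
                        is_informative=minor >= 2,
                        maf=minor / n_called,
                    )
                )
                genos.append(geno)
            j = k

    if rows:
        order = sorted(range(len(rows)), key=lambda i: rows[i]["position"])
        sites = pd.DataFrame([rows[i] for i in order])
        gmat = np.vstack([genos[i] for i in order])
    else:
        sites = pd.DataFrame(
            columns=[
                "position", "end", "type", "alleles", "counts", "n_called",
                "ancestral", "derived_count", "is_singleton", "is_informative",
                "maf",
            ]
        )
        gmat = np.zeros((0, n), dtype=np.int16)
    return VariantTable(aln.locus_id, ids, sites, gmat, aln.length)


def polarize_variants(vt: VariantTable, outgroup: np.ndarray) -> VariantTable:
    """Fill ancestral alleles and derived counts ξ from an aligned outgroup row.

    The ancestral state is the outgroup base wherever the outgroup carries one
    of the segregating alleles at that site; a missing outgroup base or a third
    allele leaves the site unpolarized (``ancestral=''``, ``derived_count=-1``).
    Indel rows are polarized by outgroup gap presence over the run.
    """
    if len(outgroup) != vt.L_total:
        raise ValueError("outgroup row length mismatch")
    sites = vt.sites.copy()
    anc_col = []
    xi_col = []
    for i, row in enumerate(sites.itertuples(index=False)):
        alleles = row.alleles.split(",")
        counts = np.array([int(c) for c in row.counts.split(",")])
        if row.type == "SNP":
            og = str(outgroup[row.position])
            anc = og if og in alleles else ""
        else:
            run = outgroup[row.position:row.end]
            if np.any(run == "N"):
                anc = ""
            else:
                anc = "absent" if np.all(run == "-") else (
                    "present" if not np.any(run == "-") else ""
                )
        if anc:
            xi = int(counts.sum() - counts[alleles.index(anc)])
            anc_col.append(anc)
            xi_col.append(xi)
        else:
            anc_col.append("")
            xi_col.append(-1)
    sites["ancestral"] = anc_col
    sites["derived_count"] = xi_col
    return VariantTable(vt.locus_id, vt.sample_ids, sites, vt.genotypes, vt.L_total)


@dataclass
class HaplotypeSet:
    """Distinct full-locus haplotypes with per-group frequencies.

    ``haplotypes`` maps haplotype string -> count; ``assignments`` maps
    sample_id -> haplotype string.  Samples exceeding the missing-data
    tolerance are excluded and listed in ``excluded``.
    """

    locus_id: str
    haplotypes: dict[str, int]
    assignments: dict[str, str]
    excluded: list[str] = field(default_factory=list)

    @property
    def N(self) -> int:
        return len(self.haplotypes)

    @property
    def n(self) -> int:
        return sum(self.haplotypes.values())

    @property
    def frequencies(self) -> np.ndarray:
        counts = np.array(sorted(self.haplotypes.values(), reverse=True), float)
        return counts / counts.sum()

    @property
    def homozygosity(self) -> float:
        """Ewens–Watterson F = Σ p_i²."""
        p = self.frequencies
        return float(np.sum(p * p))


def extract_haplotypes(
    aln: LocusAlignment,
    subset: Sequence[str] | None = None,
    max_missing_frac: float = 0.2,
) -> HaplotypeSet:
    """Haplotypes keyed on the full locus sequence (indels included).

    Samples with more than ``max_missing_frac`` N over the locus are excluded
    from haplotype calling; remaining N columns are kept verbatim so two
    sequences differing only in an N position count as distinct haplotypes
    only if their called characters differ (N matches nothing: sequences are
    compared as raw strings, so a residual N does separate haplotypes — hence
    the missing-data gate).
    """
    mat = aln.rows(subset)
    ids = aln.subset_ids(subset)
    if len(ids) < 1:
        raise ValueError("empty subset")
    haplotypes: dict[str, int] = {}
    assignments: dict[str, str] = {}
    excluded = []
    for sid, row in zip(ids, mat):
        if (row == "N").mean() > max_missing_frac:
            excluded.append(sid)
            continue
        h = "".join(row)
        haplotypes[h] = haplotypes.get(h, 0) + 1
        assignments[sid] = h
    if not haplotypes:
        raise ValueError(
            f"locus {aln.locus_id}: no samples passed the missing-data filter"
        )
    return HaplotypeSet(aln.locus_id, haplotypes, assignments, excluded)
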