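"""Study loading and result export.

A *study* is described by a flat ``key = value`` config file (format version
1, line comments with ``#``)::

    # pinepop study config
    version = 1
    samples = samples.tsv
    loci = loci.tsv
    annotation = annotation.tsv      # optional
    outgroup_record = OUTGROUP       # optional, default "OUTGROUP"

Relative paths are resolved against the config file's directory.

``samples.tsv`` columns: sample_id, taxon, population, region (region may be
empty).  ``loci.tsv`` columns: locus_id, fasta, is_mtdna (0/1, optional,
default 0), outgroup_fasta (optional path; alternatively the locus FASTA may
contain a record named by ``outgroup_record`` which is split off as the
outgroup row).  ``annotation.tsv`` columns: locus_id, start, end, frame with
0-based half-open coordinates in alignment space.

Report writers use 1-based coordinates (VCF convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    HaplotypeSet,
    LocusAlignment,
    SampleRecord,
    SampleTable,
    SiteAnnotation,
    VariantTable,
)

__all__ = ["StudyData", "load_study", "write_vcf", "write_run_summary", "write_newick"]


@dataclass
class StudyData:
    """All inputs of one study, cross-validated."""

    samples: SampleTable
    alignments: dict[str, LocusAlignment]
    annotations: dict[str, SiteAnnotation] = field(default_factory=dict)
    mtdna_ids: list[str] = field(default_factory=list)
    coverage: pd.DataFrame | None = None
    low_coverage_loci: list[str] = field(default_factory=list)

    @property
    def nuclear_ids(self) -> list[str]:
        return [l for l in self.alignments if l not in set(self.mtdna_ids)]

    def taxa(self) -> dict[str, list[str]]:
        return self.samples.group("taxon")

    def populations(self) -> dict[str, list[str]]:
        return self.samples.group("population")


def _parse_config(path: Path) -> dict[str, str]:
    cfg: dict[str, str] = {}
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, val = line.split("=", 1)
        cfg[key.strip()] = val.strip()
    if cfg.get("version", "1") != "1":
        raise ValueError(f"unsupported config version {cfg.get('version')!r}")
    return cfg


def load_study(config_path: str | Path) -> StudyData:
    """Load and cross-validate a study from its config file.

    Raises on missing files, duplicate locus ids and alignment samples absent
    from the metadata.  Produces a per-locus coverage report; loci in which
    more than half of the metadata samples are missing are flagged in
    ``low_coverage_loci``.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise FileNotFoundError(config_path)
    cfg = _parse_config(config_path)
    base = config_path.parent

    def resolve(key: str) -> Path:
        p = Path(cfg[key])
        return p if p.is_absolute() else base / p

    for key in ("samples", "loci"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
        if not resolve(key).exists():
            raise FileNotFoundError(resolve(key))

    sdf = pd.read_csv(resolve("samples"), sep="\t", dtype=str).fillna("")
    samples = SampleTable(
        SampleRecord(r.sample_id, r.taxon, r.population, getattr(r, "region", ""))
        for r in sdf.itertuples(index=False)
    )

    manifest = pd.read_csv(resolve("loci"), sep="\t", dtype=str).fillna("")
    if manifest["locus_id"].duplicated().any():
        dupes = manifest.loc[manifest["locus_id"].duplicated(), "locus_id"].tolist()
        raise ValueError(f"duplicate locus ids in manifest: {dupes}")
    if len(manifest) == 0:
        raise ValueError("empty locus manifest")
    og_name = cfg.get("outgroup_record", "OUTGROUP")

    alignments: dict[str, LocusAlignment] = {}
    mtdna_ids: list[str] = []
    cov_rows = []
    for row in manifest.itertuples(index=False):
        fasta = Path(row.fasta)
        fasta = fasta if fasta.is_absolute() else base / fasta
        if not fasta.exists():
            raise FileNotFoundError(f"locus {row.locus_id}: {fasta}")
        recs = list(SeqIO.parse(str(fasta), "fasta"))
        outgroup = None
        ids, seqs = [], []
        for rec in recs:
            if rec.id == og_name:
                outgroup = str(rec.seq)
            else:
                ids.append(rec.id)
                seqs.append(str(rec.seq))
        og_path = getattr(row, "outgroup_fasta", "")
        if og_path:
            ogf = Path(og_path)
            ogf = ogf if ogf.is_absolute() else base / ogf
            if not ogf.exists():
                raise FileNotFoundError(f"locus {row.locus_id} outgroup: {ogf}")
            outgroup = str(next(SeqIO.parse(str(ogf), "fasta")).seq)
        unknown = [s for s in ids if s not in samples]
        if unknown:
            raise ValueError(
                f"locus {row.locus_id}: samples missing from metadata: {unknown}"
            )
        aln = LocusAlignment(row.locus_id, ids, seqs, outgroup)
        alignments[row.locus_id] = aln
        if getattr(row, "is_mtdna", "0") in ("1", "true", "True"):
            mtdna_ids.append(row.locus_id)
        cov_rows.append(
            dict(
                locus_id=row.locus_id,
                n_samples=len(ids),
                n_metadata=len(samples),
                coverage=len(ids) / len(samples),
                has_outgroup=outgroup is not None,
            )
        )
    coverage = pd.DataFrame(cov_rows)
    low = coverage.loc[coverage["coverage"] < 0.5, "locus_id"].tolist()

    annotations: dict[str, SiteAnnotation] = {}
    if cfg.get("annotation"):
        apath = resolve("annotation")
        if not apath.exists():
            raise FileNotFoundError(apath)
        adf = pd.read_csv(apath, sep="\t")
        for locus_id, grp in adf.groupby("locus_id"):
            ann = SiteAnnotation(
                str(locus_id),
                [(int(r.start), int(r.end), int(r.frame)) for r in grp.itertuples()],
            )
            if str(locus_id) in alignments:
                ann.validate(alignments[str(locus_id)].length)
            annotations[str(locus_id)] = ann

    return StudyData(samples, alignments, annotations, mtdna_ids, coverage, low)


def write_vcf(
    vt: VariantTable,
    path: str | Path,
    ref_source: str = "major",
) -> None:
    """Write the SNP rows of a variant table as a minimal haploid VCF 4.2.

    REF is the first (major) allele; remaining alleles become ALT.  Positions
    are 1-based.  Indel events are encoded as symbolic <DEL>-style records
    with an END info key.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=pinepop",
        f"##contig=<ID={vt.locus_id},length={vt.L_total}>",
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of indel run">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(vt.sample_ids),
    ]
    for i, row in enumerate(vt.sites.itertuples(index=False)):
        alleles = row.alleles.split(",")
        if row.type == "SNP":
            ref, alts = alleles[0], alleles[1:]
            info = "."
        else:
            ref, alts = "N", ["<DEL>"]
            info = f"END={row.end}"
        gts = ["." if g < 0 else str(g) for g in vt.genotypes[i]]
        lines.append(
            "\t".join(
                [
                    vt.locus_id,
                    str(row.position + 1),
                    f"{vt.locus_id}_{row.position + 1}",
                    ref,
                    ",".join(alts) if alts else ".",
                    ".",
                    "PASS",
                    info,
                    "GT",
                ]
                + gts
            )
        )
    path.write_text("\n".join(lines) + "\n")


def write_run_summary(path: str | Path, seed: int | None, settings: dict) -> None:
    """JSON run summary recording the seed and analysis settings."""
    import pinepop

    payload = {
        "package": "pinepop",
        "version": getattr(pinepop, "__version__", "unknown"),
        "seed": seed,
        "settings": settings,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_newick(path: str | Path, newicks: Sequence[str]) -> None:
    Path(path).write_text("\n".join(newicks) + "\n")


def write_study(study: StudyData, out_dir: str | Path) -> Path:
    """Write a StudyData back to disk in the documented layout; returns the
    config path (used by the synthetic generator and round-trip tests)."""
    out = Path(out_dir)
    (out / "loci").mkdir(parents=True, exist_ok=True)
    study.samples.to_frame().to_csv(out / "samples.tsv", sep="\t", index=False)
    man_rows = []
    for locus_id, aln in study.alignments.items():
        fasta = out / "loci" / f"{locus_id}.fasta"
        with open(fasta, "w") as fh:
            for sid, row in zip(aln.sample_ids, aln.matrix):
                fh.write(f">{sid}\n{''.join(row)}\n")
            if aln.outgroup is not None:
                fh.write(f">OUTGROUP\n{''.join(aln.outgroup)}\n")
        man_rows.append(
            dict(
                locus_id=locus_id,
                fasta=f"loci/{locus_id}.fasta",
                is_mtdna=int(locus_id in set(study.mtdna_ids)),
            )
        )
    pd.DataFrame(man_rows).to_csv(out / "loci.tsv", sep="\t", index=False)
    cfg_lines = ["version = 1", "samples = samples.tsv", "loci = loci.tsv"]
    if study.annotations:
        arows = []
        for ann in study.annotations.values():
            for s, e, f in ann.coding_intervals:
                arows.append(dict(locus_id=ann.locus_id, start=s, end=e, frame=f))
        pd.DataFrame(arows).to_csv(out / "annotation.tsv", sep="\t", index=False)
        cfg_lines.append("annotation = annotation.tsv")
    cfg = out / "study.cfg"
    cfg.write_text("\n".join(cfg_lines) + "\n")
    return cfg
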