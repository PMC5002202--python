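"""Readers and writers for the pipeline's file formats.

VCF v4.2 through pysam; PED (6-column), BED (3-5 column with a documented
label/first-exon extension), per-base depth tables (chromosome, 1-based
position, depth — the ``samtools depth`` dialect), effect/score/SV tables as
TSV through pandas.  Variant coordinates are 1-based, intervals 0-based
half-open; conversions happen here and nowhere else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import (
    GenomicInterval,
    GenotypeCall,
    NormalizedVariant,
    VariantRecord,
    left_normalize,
    split_multiallelic,
)
from .founders import Individual, Pedigree

__all__ = [
    "CohortGenotypes",
    "read_vcf_records",
    "load_cohort",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_bed",
    "write_bed",
    "read_depth_table",
    "write_depth_table",
    "read_fasta",
    "write_fasta",
]

_SEX_CODE = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_PHENO_CODE = {"1": "unaffected", "2": "affected"}
_PHENO_OUT = {"unaffected": "1", "affected": "2", "unknown": "0"}


@dataclass
class CohortGenotypes:
    """Biallelic variants x samples alternate-allele count matrix.

    ``alt_counts[i, j]`` is the alt-allele count of sample j at variant i,
    with -1 marking an explicitly missing call; ``ploidy`` carries 1 for
    hemizygous calls.  Samples absent from a record are 0 (reference), never
    missing, because a multi-sample VCF genotypes every sample at every site.
    """

    samples: list[str]
    variants: list[NormalizedVariant]
    alt_counts: np.ndarray
    ploidy: np.ndarray

    def __post_init__(self) -> None:
        self._sample_idx = {s: j for j, s in enumerate(self.samples)}
        self._var_idx = {v.key: i for i, v in enumerate(self.variants)}

    def call(self, variant: NormalizedVariant, sample: str) -> GenotypeCall:
        i = self._var_idx[variant.key]
        j = self._sample_idx[sample]
        c = int(self.alt_counts[i, j])
        p = int(self.ploidy[i, j])
        if c < 0:
            return GenotypeCall(sample, 0, p, missing=True)
        return GenotypeCall(sample, c, p)

    def calls_at(self, variant: NormalizedVariant) -> dict[str, GenotypeCall]:
        return {s: self.call(variant, s) for s in self.samples}

    def row(self, variant: NormalizedVariant) -> np.ndarray:
        return self.alt_counts[self._var_idx[variant.key]]

    def sample_index(self, sample: str) -> int:
        return self._sample_idx[sample]


def read_vcf_records(path: str | os.PathLike) -> tuple[list[str], list[VariantRecord]]:
    """Read a (possibly multiallelic) VCF into raw records."""
    with pysam.VariantFile(os.fspath(path)) as vf:
        samples = list(vf.header.samples)
        records = []
        for rec in vf:
            gts = {}
            for s in samples:
                gt = rec.samples[s].get("GT", (None,))
                if gt is None:
                    gt = (None,)
                gts[s] = tuple(gt)
            records.append(
                VariantRecord(
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    tuple(a for a in (rec.alts or ())),
                    gts,
                )
            )
    return samples, records


def load_cohort(
    path: str | os.PathLike,
    reference: Mapping[str, str] | None = None,
) -> CohortGenotypes:
    """Load a multi-sample VCF as a biallelic, (optionally) left-normalized
    cohort genotype matrix.

    Multiallelic sites are decomposed first; when ``reference`` is given each
    biallelic record is left-normalized against it.
    """
    samples, records = read_vcf_records(path)
    return cohort_from_records(samples, records, reference)


def cohort_from_records(
    samples: Sequence[str],
    records: Iterable[VariantRecord],
    reference: Mapping[str, str] | None = None,
) -> CohortGenotypes:
    """Build a cohort matrix from raw records (shared by VCF loading and the
    in-memory synthetic path)."""
    samples = list(samples)
    variants: list[NormalizedVariant] = []
    counts_rows: list[list[int]] = []
    ploidy_rows: list[list[int]] = []
    for rec in records:
        for bi in split_multiallelic(rec):
            if reference is not None:
                nv = left_normalize(bi.chrom, bi.pos, bi.ref, bi.alts[0], reference)
            else:
                nv = NormalizedVariant(bi.chrom, bi.pos, bi.ref, bi.alts[0])
            crow, prow = [], []
            for s in samples:
                alleles = bi.genotypes.get(s, (None,))
                ploidy = max(1, len(alleles))
                if any(a is None for a in alleles):
                    crow.append(-1)
                else:
                    crow.append(sum(1 for a in alleles if a == 1))
                prow.append(ploidy)
            variants.append(nv)
            counts_rows.append(crow)
            ploidy_rows.append(prow)
    return CohortGenotypes(
        samples,
        variants,
        np.asarray(counts_rows, dtype=np.int8).reshape(len(variants), len(samples)),
        np.asarray(ploidy_rows, dtype=np.int8).reshape(len(variants), len(samples)),
    )


def write_vcf(
    path: str | os.PathLike,
    contigs: Mapping[str, int],
    samples: Sequence[str],
    records: Iterable[VariantRecord],
) -> None:
    """Write raw records as an uncompressed multi-sample VCF v4.2."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vf:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alts)):
            out = vf.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
            )
            for s in samples:
                gt = rec.genotypes.get(s, (None, None))
                out.samples[s]["GT"] = gt
                out.samples[s].phased = False
            vf.write(out)


def read_ped(path: str | os.PathLike) -> list[Pedigree]:
    """Read a 6-column PED file (family, id, father, mother, sex, phenotype).

    The proband of each family is its first affected member in file order.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family", "id", "father", "mother", "sex", "phenotype"],
        dtype=str,
        comment="#",
    )
    pedigrees: list[Pedigree] = []
    for fam, group in df.groupby("family", sort=False):
        members = [
            Individual(
                id=row.id,
                sex=_SEX_CODE.get(row.sex, "unknown"),
                affected=_PHENO_CODE.get(row.phenotype, "unknown"),
                father_id=None if row.father == "0" else row.father,
                mother_id=None if row.mother == "0" else row.mother,
            )
            for row in group.itertuples()
        ]
        pedigrees.append(Pedigree(str(fam), members))
    return pedigrees


def write_ped(path: str | os.PathLike, pedigrees: Sequence[Pedigree]) -> None:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            _SEX_OUT[m.sex],
                            _PHENO_OUT[m.affected],
                        ]
                    )
                    + "\n"
                )


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/4/5; column 4 is a label, column 5 a 0/1 first-exon flag."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            first = len(parts) > 4 and parts[4] == "1"
            intervals.append(GenomicInterval(chrom, start, end, label, first))
    return intervals


def write_bed(path: str | os.PathLike, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label or iv.is_first_exon:
                fields.append(iv.label)
            if iv.is_first_exon:
                fields.append("1")
            fh.write("\t".join(fields) + "\n")


def read_depth_table(path: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Read a 3-column depth table into per-chromosome (pos, depth) frames."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "depth"],
        dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
    )
    return {str(c): g[["pos", "depth"]].reset_index(drop=True)
            for c, g in df.groupby("chrom", sort=False)}


def write_depth_table(
    path: str | os.PathLike, per_chrom: Mapping[str, pd.DataFrame]
) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(per_chrom):
            df = per_chrom[chrom].sort_values("pos")
            for pos, depth in zip(df["pos"], df["depth"]):
                fh.write(f"{chrom}\t{int(pos)}\t{int(depth)}\n")


def read_effects_table(path: str | os.PathLike):
    """Read an effect-annotation TSV (chrom, pos, ref, alt, gene,
    effect_class, splice_distance)."""
    from .segregation import EffectAnnotation

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples():
        dist = row.splice_distance
        dist = None if pd.isna(dist) or dist == "" else int(dist)
        out.append(
            EffectAnnotation(
                (str(row.chrom), int(row.pos), str(row.ref), str(row.alt)),
                str(row.gene),
                str(row.effect_class),
                dist,
            )
        )
    return out


def read_scores_table(path: str | os.PathLike) -> pd.DataFrame:
    """Deleteriousness scores TSV: chrom, pos, ref, alt, raw, phred."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_known_positions(path: str | os.PathLike) -> list[tuple[str, int, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [(str(r.chrom), int(r.pos), str(r.gene)) for r in df.itertuples()]


def read_sv_table(path: str | os.PathLike):
    """Per-sample SV call TSV: sample, type, chrom, pos, size, sequence,
    support.  Returns {sample: [StructuralVariantCall, ...]}."""
    from .indels import StructuralVariantCall

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sequence": str})
    out: dict[str, list] = {}
    for row in df.itertuples():
        seq = None if pd.isna(row.sequence) or row.sequence == "" else str(row.sequence)
        out.setdefault(str(row.sample), []).append(
            StructuralVariantCall(
                str(row.type), str(row.chrom), int(row.pos), int(row.size),
                seq, int(row.support),
            )
        )
    return out


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a small FASTA into an in-memory name->sequence mapping."""
    import pyfaidx

    with pyfaidx.Fasta(os.fspath(path), as_raw=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str | os.PathLike, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
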