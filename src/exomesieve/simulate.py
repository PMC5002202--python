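"""Synthetic cohort generator.

Emits every input the analysis consumes — reference FASTA, exon/target BED,
PED, multi-sample VCF, effect annotations, per-base depth tables, non-exonic
variant set with deleteriousness scores, and structural-variant call sets —
with the statistical structure the analyses assume: nuclear families of a
proband, two unaffected parents and unaffected siblings; founder genotypes
in Hardy-Weinberg proportions from a spectrum of common variants plus a rare
tail; Mendelian transmission to children; causal variants planted under the
four inheritance models; on-target read depth with first-exon dips and
exponential off-target decay on the scale of the sequencing insert;
non-exonic positions concentrated within a few hundred bases of exons; and
deletion/insertion calls whose redundancy with the genotype caller falls off
with size.

Everything is drawn from a single integer seed through fixed per-stage
sub-streams, so identical config + seed reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import GenomicInterval, NormalizedVariant, VariantRecord
from .coverage import DepthTrack
from .founders import Individual, Pedigree
from .indels import StructuralVariantCall
from .segregation import EffectAnnotation

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "ConfigError"]

_BASES = np.array(list("ACGT"))

# fixed sub-stream keys: adding a stage never perturbs earlier outputs
_STREAMS = {
    "reference": 0,
    "annotation": 1,
    "cohort": 2,
    "planted": 3,
    "depth": 4,
    "noncoding": 5,
    "sv": 6,
}


class ConfigError(ValueError):
    """A simulation-config field failed validation."""

    def __init__(self, fld: str, message: str):
        super().__init__(f"config field {fld!r}: {message}")
        self.field = fld


@dataclass
class SimulationConfig:
    """Study-shaped defaults; the paper-shape preset scales to 54 families."""

    seed: int = 0
    n_families: int = 6
    family_size: int = 6  # proband + both parents + 3 siblings

    # genome model
    n_genes: int = 30
    exons_per_gene: int = 4
    exon_length: int = 120
    intron_length: int = 400
    intergenic_length: int = 1500
    single_exon_gene_fraction: float = 0.1
    x_gene_fraction: float = 0.15
    target_exon_fraction: float = 0.9
    n_known_positions: int = 40

    # founder allele-frequency spectrum
    n_variants: int = 1500
    multiallelic_fraction: float = 0.05
    common_fraction: float = 0.55
    common_maf_low: float = 0.05
    common_maf_high: float = 0.5
    rare_maf: float = 0.01
    missing_rate: float = 0.0
    plant_causal: bool = True

    # effect-annotation mix (allowed, other, intronic-near-splice)
    effect_allowed_fraction: float = 0.6
    effect_intronic_fraction: float = 0.15

    # depth model
    mean_depth: float = 80.0
    first_exon_dip: float = 0.35
    exon_dropout_rate: float = 0.03
    # capture-failure exons shared by every sample (the consistently-low set)
    systematic_low_exon_fraction: float = 0.05
    systematic_low_factor: float = 0.05
    # rare per-base holes inside otherwise covered exons (partial-zero exons)
    base_dropout_rate: float = 0.0002
    insert_size: int = 280
    depth_flank: int = 400

    # non-exonic variants
    n_noncoding: int = 1000
    noncoding_decay: float = 180.0
    noncoding_far_fraction: float = 0.08
    noncoding_common_fraction: float = 0.8
    benign_fraction: float = 0.47
    phred_scale: float = 3.2

    # structural variants
    n_sv_events: int = 250
    sv_common_fraction: float = 0.55
    sv_min_size: int = 1
    sv_max_size: int = 16000
    sv_denovo_per_proband: int = 3
    sv_caller_probs: tuple = ((10, 0.72), (50, 0.66), (100, 0.35), (10**9, 0.05))
    sv_caller_probs_ins: tuple = ((10, 0.70), (50, 0.40), (100, 0.15), (10**9, 0.05))

    def validate(self) -> None:
        for fld in (
            "single_exon_gene_fraction", "x_gene_fraction", "target_exon_fraction",
            "multiallelic_fraction", "common_fraction", "rare_maf", "missing_rate",
            "effect_allowed_fraction", "effect_intronic_fraction",
            "exon_dropout_rate", "systematic_low_exon_fraction",
            "systematic_low_factor", "base_dropout_rate",
            "noncoding_far_fraction",
            "noncoding_common_fraction", "benign_fraction", "sv_common_fraction",
        ):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(fld, f"must be a rate in [0, 1], got {v}")
        for fld in ("n_families", "family_size", "n_genes", "exons_per_gene",
                    "exon_length", "intron_length", "intergenic_length",
                    "n_variants"):
            if getattr(self, fld) < 1:
                raise ConfigError(fld, "must be a positive integer")
        if self.family_size < 3:
            raise ConfigError("family_size", "needs at least proband + parents")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed", "a seed integer is mandatory")
        if self.first_exon_dip < 0:
            raise ConfigError("first_exon_dip", "must be >= 0")
        if self.common_maf_low >= self.common_maf_high:
            raise ConfigError("common_maf_low", "must be < common_maf_high")
        if self.plant_causal and self.n_families < 4:
            raise ConfigError(
                "n_families", "planting all four models needs >= 4 families"
            )

    @classmethod
    def paper_shape(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """54-family preset mirroring the study cohort's shape."""
        kw = dict(n_families=54, n_variants=2000)
        kw.update(overrides)
        return cls(seed=seed, **kw)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("<root>", "config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                raise ConfigError(key, "unknown field")
        cfg = cls(**raw)
        # YAML has no tuple type; normalize the step tables
        for fld in ("sv_caller_probs", "sv_caller_probs_ins"):
            setattr(cfg, fld, tuple(tuple(x) for x in getattr(cfg, fld)))
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class GeneModel:
    name: str
    chrom: str
    exons: list[GenomicInterval]


@dataclass
class SimulatedDataset:
    """In-memory synthetic study; ``write`` emits the on-disk formats."""

    config: SimulationConfig
    reference: dict[str, str]
    genes: list[GeneModel]
    exons: list[GenomicInterval]
    targets: list[GenomicInterval]
    known_positions: list[tuple[str, int, str]]
    pedigrees: list[Pedigree]
    samples: list[str]
    cohort_records: list[VariantRecord]
    annotations: list[EffectAnnotation]
    truth: dict[str, list[dict]]
    depth: dict[str, DepthTrack]
    depth_rows: dict[str, list[tuple[str, int, int]]]
    noncoding_records: list[VariantRecord]
    noncoding_samples: list[str]
    scores: pd.DataFrame
    sv_calls: dict[str, list[StructuralVariantCall]]
    caller_indels: dict[str, list[NormalizedVariant]]

    @property
    def contigs(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}

    @property
    def probands(self) -> list[str]:
        return [p.proband_id for p in self.pedigrees]

    def cohort(self):
        from .io import cohort_from_records

        return cohort_from_records(self.samples, self.cohort_records, self.reference)

    def noncoding_cohort(self):
        from .io import cohort_from_records

        return cohort_from_records(
            self.noncoding_samples, self.noncoding_records, self.reference
        )

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        from . import io as esio

        out = os.fspath(out_dir)
        os.makedirs(out, exist_ok=True)
        paths: dict[str, str] = {}

        def p(name: str) -> str:
            paths[name] = os.path.join(out, name)
            return paths[name]

        esio.write_fasta(p("reference.fa"), self.reference)
        esio.write_bed(p("exons.bed"), self.exons)
        esio.write_bed(p("targets.bed"), self.targets)
        with open(p("known_positions.tsv"), "w") as fh:
            fh.write("chrom\tpos\tgene\n")
            for c, pos, g in self.known_positions:
                fh.write(f"{c}\t{pos}\t{g}\n")
        esio.write_ped(p("cohort.ped"), self.pedigrees)
        esio.write_vcf(p("cohort.vcf"), self.contigs, self.samples, self.cohort_records)
        ann = pd.DataFrame(
            [
                {
                    "chrom": a.key[0], "pos": a.key[1], "ref": a.key[2],
                    "alt": a.key[3], "gene": a.gene,
                    "effect_class": a.effect_class,
                    "splice_distance": "" if a.splice_distance is None else a.splice_distance,
                }
                for a in self.annotations
            ]
        )
        ann.to_csv(p("effects.tsv"), sep="\t", index=False)
        for sample, rows in self.depth_rows.items():
            with open(p(f"depth_{sample}.tsv"), "w") as fh:
                for chrom, pos, depth in rows:
                    fh.write(f"{chrom}\t{pos}\t{depth}\n")
        esio.write_vcf(
            p("noncoding.vcf"), self.contigs, self.noncoding_samples,
            self.noncoding_records,
        )
        self.scores.to_csv(p("scores.tsv"), sep="\t", index=False)
        sv_rows = []
        for sample in sorted(self.sv_calls):
            for c in self.sv_calls[sample]:
                sv_rows.append(
                    {
                        "sample": sample, "type": c.sv_type, "chrom": c.chrom,
                        "pos": c.pos, "size": c.size,
                        "sequence": c.sequence or "", "support": c.support,
                    }
                )
        pd.DataFrame(sv_rows).to_csv(p("sv_calls.tsv"), sep="\t", index=False)
        for sample in sorted(self.caller_indels):
            recs = [
                VariantRecord(v.chrom, v.pos, v.ref, (v.alt,), {sample: (0, 1)})
                for v in self.caller_indels[sample]
            ]
            esio.write_vcf(
                p(f"caller_indels_{sample}.vcf"), self.contigs, [sample], recs
            )
        import json

        with open(p("truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        return paths


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(_STREAMS[stage],))
    )


def _simulate_annotation(config: SimulationConfig):
    rng = _rng(config, "annotation")
    n_x = max(1, int(round(config.x_gene_fraction * config.n_genes)))
    genes: list[GeneModel] = []
    exons: list[GenomicInterval] = []
    lengths: dict[str, int] = {}
    gi = 0
    for chrom, n_chrom_genes in (("chr1", config.n_genes - n_x), ("chrX", n_x)):
        cursor = config.intergenic_length
        for _ in range(n_chrom_genes):
            name = f"GENE{gi:04d}"
            gi += 1
            n_ex = (
                1
                if rng.random() < config.single_exon_gene_fraction
                else config.exons_per_gene
            )
            gene_exons = []
            for rank in range(n_ex):
                start = cursor
                end = start + config.exon_length
                gene_exons.append(
                    GenomicInterval(chrom, start, end, name, is_first_exon=(rank == 0))
                )
                cursor = end + config.intron_length
            cursor += config.intergenic_length
            genes.append(GeneModel(name, chrom, gene_exons))
            exons.extend(gene_exons)
        lengths[chrom] = cursor + config.intergenic_length
    # capture targets: a subset of exons, padded slightly
    targets = [
        GenomicInterval(e.chrom, max(0, e.start - 10), e.end + 10)
        for e in exons
        if rng.random() < config.target_exon_fraction
    ]
    if not targets:
        raise ConfigError("target_exon_fraction", "no exon was targeted")
    # known disease-variant positions: random exonic bases with gene labels
    known = []
    for _ in range(config.n_known_positions):
        e = exons[rng.integers(len(exons))]
        pos = int(rng.integers(e.start + 1, e.end + 1))
        known.append((e.chrom, pos, e.label))
    return genes, exons, targets, known, lengths


def _simulate_reference(config: SimulationConfig, lengths: Mapping[str, int]):
    rng = _rng(config, "reference")
    return {
        chrom: "".join(_BASES[rng.integers(0, 4, size=length)])
        for chrom, length in lengths.items()
    }


def _make_pedigrees(config: SimulationConfig) -> list[Pedigree]:
    pedigrees = []
    for i in range(config.n_families):
        fam = f"F{i:03d}"
        father = Individual(f"{fam}_fa", "male", "unaffected")
        mother = Individual(f"{fam}_mo", "female", "unaffected")
        members = [father, mother]
        proband = Individual(
            f"{fam}_p", "male", "affected", father.id, mother.id
        )
        members.append(proband)
        sib_sexes = ["female", "male", "female", "male"]
        for j in range(config.family_size - 3):
            members.append(
                Individual(
                    f"{fam}_s{j}", sib_sexes[j % 4], "unaffected",
                    father.id, mother.id,
                )
            )
        pedigrees.append(Pedigree(fam, members, proband_id=proband.id))
    return pedigrees


def _transmit(rng, father_gt, mother_gt, sex, chrom_class):
    """Mendelian transmission of one site; returns child allele tuple."""
    if chrom_class == "X":
        m_allele = mother_gt[rng.integers(len(mother_gt))]
        if sex == "male":
            return (m_allele,)
        return (father_gt[rng.integers(len(father_gt))], m_allele)
    return (
        father_gt[rng.integers(len(father_gt))],
        mother_gt[rng.integers(len(mother_gt))],
    )


def _simulate_cohort(config: SimulationConfig, genes, exons, reference, pedigrees):
    rng = _rng(config, "cohort")
    exonic = [(e.chrom, int(p), e.label) for e in exons for p in range(e.start + 1, e.end + 1)]
    order = rng.permutation(len(exonic))
    n_sites = min(config.n_variants, len(exonic))
    sites = [exonic[i] for i in order[:n_sites]]

    samples = [m.id for ped in pedigrees for m in ped.members]
    sex_of = {m.id: m.sex for ped in pedigrees for m in ped.members}

    records: list[VariantRecord] = []
    annotations: list[EffectAnnotation] = []
    allowed_pool = [
        "non_synonymous", "non_synonymous", "frameshift", "canonical_splice",
        "stop_gain_loss", "start_gain_loss",
    ]
    for chrom, pos, gene in sites:
        from .core import chromosome_class

        cls = chromosome_class(chrom)
        ref = reference[chrom][pos - 1]
        alt_choices = [b for b in "ACGT" if b != ref]
        multi = rng.random() < config.multiallelic_fraction
        alts = tuple(
            str(a) for a in rng.choice(alt_choices, size=2, replace=False)
        ) if multi else (str(rng.choice(alt_choices)),)
        if rng.random() < config.common_fraction:
            maf = float(rng.uniform(config.common_maf_low, config.common_maf_high))
        else:
            maf = config.rare_maf
        freqs = [maf] + ([maf / 4] if multi else [])

        gts: dict[str, tuple] = {}
        for ped in pedigrees:
            for member in ped.members:
                if member.is_founder:
                    ploidy = (
                        1 if cls == "X" and member.sex == "male" else 2
                    )
                    alleles = []
                    for _ in range(ploidy):
                        u = rng.random()
                        a = 0
                        acc = 0.0
                        for ai, f in enumerate(freqs, start=1):
                            acc += f
                            if u < acc:
                                a = ai
                                break
                        alleles.append(a)
                    gts[member.id] = tuple(alleles)
            father = next(m for m in ped.members if m.sex == "male" and m.is_founder)
            mother = next(m for m in ped.members if m.sex == "female" and m.is_founder)
            for member in ped.members:
                if not member.is_founder:
                    gts[member.id] = _transmit(
                        rng, gts[father.id], gts[mother.id], member.sex, cls
                    )
        if config.missing_rate > 0:
            for s in samples:
                if rng.random() < config.missing_rate:
                    gts[s] = tuple(None for _ in gts[s])
        records.append(VariantRecord(chrom, pos, ref, alts, gts))
        for alt in alts:
            u = rng.random()
            if u < config.effect_allowed_fraction:
                eff, dist = str(rng.choice(allowed_pool)), None
            elif u < config.effect_allowed_fraction + config.effect_intronic_fraction:
                eff, dist = "intronic_near_splice", int(rng.integers(1, 41))
            else:
                eff, dist = "other", None
            annotations.append(
                EffectAnnotation((chrom, pos, ref, alt), gene, eff, dist)
            )
    return samples, sex_of, records, annotations


def _plant_causal(config, genes, reference, pedigrees, records, annotations):
    """Insert one causal variant (or pair) per model into the first four
    families; genotypes exactly satisfy each model, founders of all other
    families stay homozygous reference."""
    rng = _rng(config, "planted")
    used_positions = {(r.chrom, r.pos) for r in records}
    autosomal_genes = [g for g in genes if g.chrom != "chrX"]
    x_genes = [g for g in genes if g.chrom == "chrX"]
    if not x_genes:
        raise ConfigError("x_gene_fraction", "planting x_linked needs an X gene")
    all_samples = [m.id for ped in pedigrees for m in ped.members]

    def fresh_position(gene: GeneModel, forbidden=()):
        for _ in range(1000):
            e = gene.exons[rng.integers(len(gene.exons))]
            pos = int(rng.integers(e.start + 1, e.end + 1))
            if (gene.chrom, pos) not in used_positions and pos not in forbidden:
                used_positions.add((gene.chrom, pos))
                return pos
        raise ConfigError("n_variants", "no free exonic position to plant into")

    def base_record(chrom, pos):
        ref = reference[chrom][pos - 1]
        alt = "A" if ref != "A" else "G"
        cls_x = chrom == "chrX"
        gts = {}
        for ped in pedigrees:
            for m in ped.members:
                ploidy = 1 if cls_x and m.sex == "male" else 2
                gts[m.id] = tuple([0] * ploidy)
        return VariantRecord(chrom, pos, ref, (alt,), gts)

    truth: dict[str, list[dict]] = {}
    gene_cursor = iter(rng.permutation(len(autosomal_genes)))

    def next_autosomal_gene() -> GeneModel:
        return autosomal_genes[next(gene_cursor)]

    def add(record, gene, fam, model):
        records.append(record)
        key = (record.chrom, record.pos, record.ref, record.alts[0])
        annotations.append(EffectAnnotation(key, gene.name, "frameshift", None))
        truth.setdefault(fam, []).append(
            {"model": model, "keys": [list(key)], "gene": gene.name}
        )
        return key

    fams = pedigrees[:4]

    # de novo dominant: proband het, everyone else reference
    ped = fams[0]
    gene = next_autosomal_gene()
    rec = base_record(gene.chrom, fresh_position(gene))
    rec.genotypes[ped.proband_id] = (0, 1)
    add(rec, gene, ped.family_id, "de_novo_dominant")

    # homozygous recessive: parents het, proband hom, sibs het/ref
    ped = fams[1]
    gene = next_autosomal_gene()
    rec = base_record(gene.chrom, fresh_position(gene))
    father, mother = (p.id for p in ped.parents_of(ped.proband_id))
    rec.genotypes[father] = (0, 1)
    rec.genotypes[mother] = (1, 0)
    rec.genotypes[ped.proband_id] = (1, 1)
    for s in ped.siblings_of(ped.proband_id):
        rec.genotypes[s.id] = (int(rng.integers(0, 2)), 0)
    add(rec, gene, ped.family_id, "hom_recessive")

    # compound heterozygous: two variants in one gene, opposite origins
    ped = fams[2]
    gene = next_autosomal_gene()
    pos_a = fresh_position(gene)
    pos_b = fresh_position(gene, forbidden={pos_a})
    rec_a = base_record(gene.chrom, pos_a)
    rec_b = base_record(gene.chrom, pos_b)
    father, mother = (p.id for p in ped.parents_of(ped.proband_id))
    rec_a.genotypes[father] = (0, 1)
    rec_a.genotypes[ped.proband_id] = (1, 0)
    rec_b.genotypes[mother] = (0, 1)
    rec_b.genotypes[ped.proband_id] = (0, 1)
    records.append(rec_a)
    records.append(rec_b)
    key_a = (rec_a.chrom, rec_a.pos, rec_a.ref, rec_a.alts[0])
    key_b = (rec_b.chrom, rec_b.pos, rec_b.ref, rec_b.alts[0])
    annotations.append(EffectAnnotation(key_a, gene.name, "frameshift", None))
    annotations.append(EffectAnnotation(key_b, gene.name, "non_synonymous", None))
    truth.setdefault(ped.family_id, []).append(
        {"model": "compound_het", "keys": [list(key_a), list(key_b)], "gene": gene.name}
    )

    # X-linked: male proband hemizygous alt, carrier mother, clean father
    ped = fams[3]
    gene = x_genes[int(rng.integers(len(x_genes)))]
    rec = base_record(gene.chrom, fresh_position(gene))
    father, mother = (p.id for p in ped.parents_of(ped.proband_id))
    rec.genotypes[mother] = (1, 0)
    rec.genotypes[ped.proband_id] = (1,)
    add(rec, gene, ped.family_id, "x_linked")

    return truth


def _simulate_depth(config: SimulationConfig, exons, probands):
    rng = _rng(config, "depth")
    # capture-failure exons are a property of the assay, shared by samples
    systematic = rng.random(len(exons)) < config.systematic_low_exon_fraction
    tracks: dict[str, DepthTrack] = {}
    rows_by_sample: dict[str, list[tuple[str, int, int]]] = {}
    for sample in probands:
        chrom_parts: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        for ei, e in enumerate(exons):
            rate = config.mean_depth * (
                config.first_exon_dip if e.is_first_exon else 1.0
            )
            if systematic[ei]:
                rate *= config.systematic_low_factor
            if rng.random() < config.exon_dropout_rate:
                rate = 0.0
            positions = np.arange(e.start + 1, e.end + 1, dtype=np.int64)
            if rate > 0:
                depths = rng.poisson(rate, size=positions.size)
                if config.base_dropout_rate > 0:
                    holes = rng.random(positions.size) < config.base_dropout_rate
                    depths[holes] = 0
            else:
                depths = np.zeros(positions.size, dtype=np.int64)
            chrom_parts.setdefault(e.chrom, []).append((positions, depths))
            # off-target flanks decay on the insert-size scale
            if rate > 0:
                for flank_positions in (
                    np.arange(
                        max(1, e.start + 1 - config.depth_flank), e.start + 1,
                        dtype=np.int64,
                    ),
                    np.arange(
                        e.end + 1, e.end + 1 + config.depth_flank, dtype=np.int64
                    ),
                ):
                    if flank_positions.size == 0:
                        continue
                    dist = np.minimum(
                        np.abs(flank_positions - (e.start + 1)),
                        np.abs(flank_positions - e.end),
                    )
                    lam = rate * np.exp(-dist / config.insert_size)
                    chrom_parts[e.chrom].append(
                        (flank_positions, rng.poisson(lam))
                    )
        rows: list[tuple[str, int, int]] = []
        per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(chrom_parts):
            pos = np.concatenate([p for p, _ in chrom_parts[chrom]])
            dep = np.concatenate([d for _, d in chrom_parts[chrom]])
            # overlapping flanks: keep the maximum depth per position
            order = np.lexsort((-dep, pos))
            pos, dep = pos[order], dep[order]
            first = np.ones(pos.size, dtype=bool)
            first[1:] = pos[1:] != pos[:-1]
            pos, dep = pos[first], dep[first]
            keep = dep > 0
            pos, dep = pos[keep], dep[keep]
            per_chrom[chrom] = (pos, dep)
            rows.extend(
                (chrom, int(p), int(d)) for p, d in zip(pos, dep)
            )
        rows_by_sample[sample] = rows
        tracks[sample] = DepthTrack(per_chrom)
    return tracks, rows_by_sample


def _simulate_noncoding(config: SimulationConfig, exons, reference, pedigrees):
    rng = _rng(config, "noncoding")
    from .noncoding import ExonDistanceIndex

    index = ExonDistanceIndex(exons)
    contig_len = {c: len(s) for c, s in reference.items()}
    exon_list = [e for e in exons if e.chrom == "chr1"]
    samples = []
    for ped in pedigrees:
        samples.extend(p.id for p in ped.founders)
        samples.append(ped.proband_id)

    positions: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    attempts = 0
    while len(positions) < config.n_noncoding and attempts < config.n_noncoding * 50:
        attempts += 1
        e = exon_list[rng.integers(len(exon_list))]
        if rng.random() < config.noncoding_far_fraction:
            d = int(rng.integers(500, 5000))
        else:
            d = 1 + int(rng.exponential(config.noncoding_decay))
        pos = e.start + 1 - d if rng.random() < 0.5 else e.end + d
        if pos < 1 or pos > contig_len[e.chrom]:
            continue
        try:
            dist, exonic = index.distance(e.chrom, pos)
        except KeyError:
            continue
        if exonic or (e.chrom, pos) in seen:
            continue
        seen.add((e.chrom, pos))
        positions.append((e.chrom, pos))

    records: list[VariantRecord] = []
    score_rows = []
    for chrom, pos in positions:
        ref = reference[chrom][pos - 1]
        alt = "T" if ref != "T" else "C"
        if rng.random() < config.noncoding_common_fraction:
            maf = float(
                rng.uniform(config.common_maf_low, config.common_maf_high)
            )
        else:
            maf = config.rare_maf
        gts = {}
        for ped in pedigrees:
            parent_gts = {}
            for p in ped.founders:
                parent_gts[p.id] = (
                    int(rng.random() < maf), int(rng.random() < maf)
                )
                gts[p.id] = parent_gts[p.id]
            fa, mo = (x.id for x in ped.parents_of(ped.proband_id))
            gts[ped.proband_id] = _transmit(
                rng, gts[fa], gts[mo], "male", "autosomal"
            )
        records.append(VariantRecord(chrom, pos, ref, (alt,), gts))
        if rng.random() < config.benign_fraction:
            raw = -float(rng.exponential(0.5)) - 1e-6
            phred = float(rng.uniform(0.001, 3.0))
        else:
            raw = float(rng.exponential(0.8))
            phred = float(rng.exponential(config.phred_scale))
        score_rows.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
             "raw": round(raw, 4), "phred": round(phred, 3)}
        )
    scores = pd.DataFrame(
        score_rows, columns=["chrom", "pos", "ref", "alt", "raw", "phred"]
    )
    return samples, records, scores


def _caller_prob(size: int, sv_type: str, config: SimulationConfig) -> float:
    table = (
        config.sv_caller_probs if sv_type == "deletion" else config.sv_caller_probs_ins
    )
    for upper, p in table:
        if abs(size) <= upper:
            return p
    return table[-1][1]


def _simulate_sv(config: SimulationConfig, reference, pedigrees):
    rng = _rng(config, "sv")
    chrom = "chr1"
    contig_len = len(reference[chrom])

    def draw_size() -> int:
        mag = int(
            np.exp(
                rng.uniform(
                    np.log(max(1, config.sv_min_size)), np.log(config.sv_max_size)
                )
            )
        )
        mag = max(config.sv_min_size, min(mag, config.sv_max_size))
        return mag

    # population event pool
    events = []
    for _ in range(config.n_sv_events):
        mag = draw_size()
        is_del = rng.random() < 0.5
        pos = int(rng.integers(100, contig_len - mag - 100))
        seq = None
        if not is_del:
            seq = "".join(_BASES[rng.integers(0, 4, size=mag)])
        freq = (
            float(rng.uniform(0.05, 0.4))
            if rng.random() < config.sv_common_fraction
            else 0.005
        )
        events.append(
            {
                "call": StructuralVariantCall(
                    "deletion" if is_del else "insertion",
                    chrom, pos, -mag if is_del else mag, seq,
                    support=int(rng.integers(3, 40)),
                ),
                "freq": freq,
            }
        )

    sv_calls: dict[str, list[StructuralVariantCall]] = {}
    caller_indels: dict[str, list[NormalizedVariant]] = {}
    from .indels import sv_to_variant

    for ped in pedigrees:
        fa, mo = (p.id for p in ped.parents_of(ped.proband_id))
        pid = ped.proband_id
        for s in (fa, mo, pid):
            sv_calls.setdefault(s, [])
        for ev in events:
            f = ev["freq"]
            in_fa = rng.random() < 1 - (1 - f) ** 2
            in_mo = rng.random() < 1 - (1 - f) ** 2
            if in_fa:
                sv_calls[fa].append(ev["call"])
            if in_mo:
                sv_calls[mo].append(ev["call"])
            inherited = (in_fa and rng.random() < 0.5) or (
                in_mo and rng.random() < 0.5
            )
            if inherited:
                sv_calls[pid].append(ev["call"])
        # rare de novo SVs unique to this proband
        for _ in range(config.sv_denovo_per_proband):
            mag = draw_size()
            is_del = rng.random() < 0.5
            pos = int(rng.integers(100, contig_len - mag - 100))
            seq = None if is_del else "".join(_BASES[rng.integers(0, 4, size=mag)])
            sv_calls[pid].append(
                StructuralVariantCall(
                    "deletion" if is_del else "insertion",
                    chrom, pos, -mag if is_del else mag, seq,
                    support=int(rng.integers(3, 15)),
                )
            )
        # caller redundancy declines with size
        caller_indels[pid] = []
        for call in sv_calls[pid]:
            if rng.random() < _caller_prob(call.size, call.sv_type, config):
                nv = sv_to_variant(call, reference)
                if nv is not None:
                    caller_indels[pid].append(nv)
    return sv_calls, caller_indels


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic study for one config + seed."""
    config.validate()
    genes, exons, targets, known, lengths = _simulate_annotation(config)
    reference = _simulate_reference(config, lengths)
    pedigrees = _make_pedigrees(config)
    samples, sex_of, records, annotations = _simulate_cohort(
        config, genes, exons, reference, pedigrees
    )
    truth: dict[str, list[dict]] = {}
    if config.plant_causal:
        truth = _plant_causal(
            config, genes, reference, pedigrees, records, annotations
        )
    probands = [p.proband_id for p in pedigrees]
    depth, depth_rows = _simulate_depth(config, exons, probands)
    nc_samples, nc_records, scores = _simulate_noncoding(
        config, exons, reference, pedigrees
    )
    sv_calls, caller_indels = _simulate_sv(config, reference, pedigrees)
    return SimulatedDataset(
        config=config,
        reference=reference,
        genes=genes,
        exons=exons,
        targets=targets,
        known_positions=known,
        pedigrees=pedigrees,
        samples=samples,
        cohort_records=records,
        annotations=annotations,
        truth=truth,
        depth=depth,
        depth_rows=depth_rows,
        noncoding_records=nc_records,
        noncoding_samples=nc_samples,
        scores=scores,
        sv_calls=sv_calls,
        caller_indels=caller_indels,
    )
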