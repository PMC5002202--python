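"""Shared variant/interval data model and allele normalization.

Variants use 1-based VCF coordinates; intervals use 0-based half-open BED
coordinates.  All conversions happen at I/O boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "NormalizedVariant",
    "GenomicInterval",
    "GenotypeCall",
    "VariantRecord",
    "ReferenceMismatchError",
    "UnsupportedAlleleError",
    "chromosome_class",
    "split_multiallelic",
    "left_normalize",
    "merge_intervals",
]

_BASES = re.compile(r"^[ACGTN]+$")
_SYMBOLIC = re.compile(r"[<>\[\]]|^\*$")

# Default chromosome-name dialect map.  Anything not listed is autosomal.
DEFAULT_CHROM_CLASSES: Mapping[str, str] = {
    "X": "X",
    "chrX": "X",
    "Y": "Y",
    "chrY": "Y",
}


class ReferenceMismatchError(ValueError):
    """The stated ref allele disagrees with the reference sequence."""

    def __init__(self, chrom: str, pos: int, stated: str, found: str):
        super().__init__(
            f"ref allele mismatch at {chrom}:{pos}: variant says {stated!r}, "
            f"reference has {found!r}"
        )
        self.chrom, self.pos = chrom, pos


class UnsupportedAlleleError(ValueError):
    """Symbolic / breakend alternate alleles are not supported."""


def chromosome_class(chrom: str, name_map: Mapping[str, str] | None = None) -> str:
    """Classify a chromosome name as ``autosomal``, ``X`` or ``Y``.

    The mapping is configurable for dialect tolerance ("X" vs "chrX");
    unmapped names are autosomal.
    """
    table = DEFAULT_CHROM_CLASSES if name_map is None else name_map
    return table.get(chrom, "autosomal")


@dataclass(frozen=True, order=True)
class NormalizedVariant:
    """Minimal, left-aligned biallelic variant (VCF convention, 1-based).

    ``ref`` and ``alt`` differ, share no removable common prefix/suffix
    beyond the single anchor base required for indels.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def chromosome_class(self, name_map: Mapping[str, str] | None = None) -> str:
        return chromosome_class(self.chrom, name_map)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with an optional gene label and first-exon flag."""

    chrom: str
    start: int
    end: int
    label: str = ""
    is_first_exon: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.is_first_exon and not self.label:
            raise ValueError("first-exon intervals must carry a gene label")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_position(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one biallelic site.

    ``alt_count`` counts alternate alleles; ``ploidy`` is 1 for hemizygous
    male X/Y calls, else 2.  Missing calls are explicit, never imputed here.
    """

    sample: str
    alt_count: int
    ploidy: int = 2
    missing: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.ploidy <= 2:
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if not self.missing and not 0 <= self.alt_count <= self.ploidy:
            raise ValueError(
                f"alt_count {self.alt_count} out of range for ploidy {self.ploidy}"
            )


@dataclass
class VariantRecord:
    """A raw (possibly multiallelic) site with per-sample genotype tuples.

    ``genotypes[sample]`` is a tuple of allele indices (0=ref, i>=1 the i-th
    alt) or ``None`` entries for missing alleles.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, tuple[int | None, ...]] = field(default_factory=dict)


def split_multiallelic(record: VariantRecord) -> list[VariantRecord]:
    """Decompose a multiallelic record into one biallelic record per alt.

    For alt ``i`` each sample's genotype keeps its ploidy; alleles equal to
    ``i`` become allele 1, every other non-missing allele becomes 0.  Total
    alternate-allele counts per sample are conserved across the outputs.

    Raises :class:`UnsupportedAlleleError` on symbolic alleles (``<DEL>``,
    breakends, ``*``).
    """
    if not record.alts:
        raise ValueError("record has no alternate allele")
    for alt in record.alts:
        if _SYMBOLIC.search(alt):
            raise UnsupportedAlleleError(
                f"symbolic alternate allele {alt!r} at {record.chrom}:{record.pos}"
            )
    out: list[VariantRecord] = []
    for i, alt in enumerate(record.alts, start=1):
        gts = {
            sample: tuple(
                None if a is None else (1 if a == i else 0) for a in alleles
            )
            for sample, alleles in record.genotypes.items()
        }
        out.append(
            VariantRecord(record.chrom, record.pos, record.ref, (alt,), gts)
        )
    return out


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Fetch reference bases [start0, end0) from a dict of strings or a
    pyfaidx/pysam-like object exposing ``fetch``/slicing."""
    if isinstance(reference, Mapping):
        return reference[chrom][start0:end0].upper()
    if hasattr(reference, "fetch"):
        return reference.fetch(chrom, start0, end0).upper()
    return str(reference[chrom][start0:end0]).upper()


def left_normalize(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference,
) -> NormalizedVariant:
    """Left-align and trim a biallelic variant to its unique minimal form.

    The algorithm repeatedly strips shared trailing bases (extending to the
    left through the reference when an allele would empty), then strips
    shared leading bases while both alleles are longer than one base.  The
    result is the left-most minimal representation of the sequence edit;
    indels keep one anchor base (VCF convention).

    Raises :class:`ReferenceMismatchError` when ``ref`` does not match the
    reference sequence at ``pos``.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValueError("empty allele; VCF indels must carry an anchor base")
    if _SYMBOLIC.search(alt) or _SYMBOLIC.search(ref):
        raise UnsupportedAlleleError(f"symbolic allele at {chrom}:{pos}")
    observed = _fetch(reference, chrom, pos - 1, pos - 1 + len(ref))
    if observed != ref:
        raise ReferenceMismatchError(chrom, pos, ref, observed)

    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise ValueError(
                        f"cannot left-extend past the start of {chrom}"
                    )
                pos -= 1
                base = _fetch(reference, chrom, pos - 1, pos)
                ref, alt = base + ref, base + alt
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return NormalizedVariant(chrom, pos, ref, alt)


def apply_edit(sequence: str, pos: int, ref: str, alt: str) -> str:
    """Apply the ref->alt substitution at 1-based ``pos`` to ``sequence``.

    Utility for equivalence checking: two representations of the same edit
    produce the same edited sequence.
    """
    i = pos - 1
    if sequence[i : i + len(ref)].upper() != ref.upper():
        raise ReferenceMismatchError("<seq>", pos, ref, sequence[i : i + len(ref)])
    return sequence[:i] + alt + sequence[i + len(ref) :]


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome (labels dropped)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged
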