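"""Medium-sized indel reconciliation against the standard genotype caller.

Split-read callers recover deletions/insertions from ~50 bases up to the
kilobase range that routine genotype callers miss.  This module classifies
such calls by capture-target proximity, partitions them into
redundant-with-caller vs unique, phases them against parental call sets
(each supported call is treated as one heterozygous allele), estimates
founder rarity from parental cohorts, and assembles the staged funnel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import defaults
from .core import GenomicInterval, NormalizedVariant, left_normalize, merge_intervals
from .founders import Pedigree, expected_allele_count, founder_frequency
from .report import FunnelReport, FunnelStage

__all__ = [
    "StructuralVariantCall",
    "ReconciliationRecord",
    "classify_target",
    "sv_to_variant",
    "match_calls",
    "phase_against_parents",
    "indel_funnel",
]


@dataclass(frozen=True)
class StructuralVariantCall:
    """One deletion/insertion call from a split-read caller.

    ``size`` is signed: negative for deletions, positive for insertions;
    magnitudes up to the ~16 kb range the caller reports.  ``sequence`` is
    the inserted sequence when known (insertions only; deletions take their
    sequence from the reference).
    """

    sv_type: str  # deletion | insertion
    chrom: str
    pos: int  # 1-based anchor base (base before the event, VCF convention)
    size: int
    sequence: str | None = None
    support: int = 0

    def __post_init__(self) -> None:
        if self.sv_type not in ("deletion", "insertion"):
            raise ValueError(f"unsupported SV type {self.sv_type!r}")
        if self.size == 0:
            raise ValueError("SV size must be nonzero")
        if (self.size < 0) != (self.sv_type == "deletion"):
            raise ValueError(
                f"size sign ({self.size}) inconsistent with type {self.sv_type}"
            )
        if self.sequence is not None and self.sv_type == "insertion":
            if len(self.sequence) != self.size:
                raise ValueError("insertion sequence length must equal size")

    @property
    def span(self) -> GenomicInterval:
        """Affected reference span, 0-based half-open (insertion: anchor base)."""
        if self.sv_type == "deletion":
            return GenomicInterval(self.chrom, self.pos, self.pos - self.size)
        return GenomicInterval(self.chrom, self.pos - 1, self.pos)


@dataclass(frozen=True)
class ReconciliationRecord:
    call: StructuralVariantCall
    in_target_flank: bool
    redundant_with_caller: bool
    phase: str = "unassigned"  # one_parent | both_parents | unassigned
    rarity: str | None = None


def classify_target(
    call: StructuralVariantCall,
    targets: Sequence[GenomicInterval],
    flank: int = defaults.TARGET_FLANK,
) -> bool:
    """True iff the call's affected span overlaps a target expanded by
    ``flank`` bases on both sides."""
    span = call.span
    for t in targets:
        if t.chrom != span.chrom:
            continue
        if span.start < t.end + flank and t.start - flank < span.end:
            return True
    return False


def sv_to_variant(
    call: StructuralVariantCall, reference: Mapping[str, str]
) -> NormalizedVariant | None:
    """Express an SV call as a left-normalized VCF-style allele pair.

    Deletions take their deleted sequence from the reference; insertions
    need ``sequence`` and return None without it (the positional fallback
    policy handles those).  The anchor base convention is the VCF one: the
    reported position is the base immediately before the event.
    """
    anchor = reference[call.chrom][call.pos - 1 : call.pos].upper()
    if call.sv_type == "deletion":
        deleted = reference[call.chrom][call.pos : call.pos - call.size].upper()
        return left_normalize(call.chrom, call.pos, anchor + deleted, anchor, reference)
    if call.sequence is None:
        return None
    return left_normalize(
        call.chrom, call.pos, anchor, anchor + call.sequence.upper(), reference
    )


def _positional_match(
    a: StructuralVariantCall,
    b: StructuralVariantCall,
    tolerance: int,
    size_ratio: float,
) -> bool:
    if a.sv_type != b.sv_type or a.chrom != b.chrom:
        return False
    if abs(a.pos - b.pos) > tolerance:
        return False
    lo, hi = sorted((abs(a.size), abs(b.size)))
    return lo / hi >= size_ratio


def _matches(
    call: StructuralVariantCall,
    others: Sequence[StructuralVariantCall],
    other_variants: Sequence[NormalizedVariant | None],
    call_variant: NormalizedVariant | None,
    policy: str,
    tolerance: int,
    size_ratio: float,
) -> bool:
    if policy not in ("exact", "positional"):
        raise ValueError(f"unknown matching policy {policy!r}")
    if policy == "exact" and call_variant is not None:
        keys = {v.key for v in other_variants if v is not None}
        if call_variant.key in keys:
            return True
        # calls lacking sequence on the other side fall through to positional
    return any(
        _positional_match(call, o, tolerance, size_ratio)
        for o, ov in zip(others, other_variants)
        if policy == "positional" or call_variant is None or ov is None
    )


class _MatchContext:
    """Pre-normalizes call sets once for repeated matching."""

    def __init__(
        self,
        reference: Mapping[str, str] | None,
        policy: str,
        tolerance: int,
        size_ratio: float,
    ):
        self.reference = reference
        self.policy = policy
        self.tolerance = tolerance
        self.size_ratio = size_ratio

    def normalize(self, calls: Sequence[StructuralVariantCall]):
        if self.reference is None or self.policy == "positional":
            return [None] * len(calls)
        return [sv_to_variant(c, self.reference) for c in calls]

    def any_match(
        self,
        call: StructuralVariantCall,
        call_variant: NormalizedVariant | None,
        others: Sequence[StructuralVariantCall],
        other_variants,
    ) -> bool:
        return _matches(
            call, others, other_variants, call_variant,
            self.policy, self.tolerance, self.size_ratio,
        )


def match_calls(
    sv_calls: Sequence[StructuralVariantCall],
    caller_indels: Sequence[StructuralVariantCall] | Sequence[NormalizedVariant],
    *,
    reference: Mapping[str, str] | None = None,
    policy: str = "exact",
    tolerance: int = defaults.SV_POSITION_TOLERANCE,
    size_ratio: float = defaults.SV_SIZE_RATIO,
    size_bins: Sequence[int] = (10, 50, 100, 500, 1000, 20000),
) -> dict:
    """Partition SV calls into redundant-with-caller vs unique.

    Default policy "exact": a call is redundant iff its left-normalized
    (chrom, pos, ref, alt) equals a caller indel's; calls whose inserted
    sequence is unknown fall back to the positional policy (same type,
    |Δpos| <= tolerance, size ratio >= size_ratio).  Also reports
    size-binned redundancy fractions separately for deletions/insertions.
    """
    if caller_indels and isinstance(caller_indels[0], NormalizedVariant):
        # SNVs in the caller set can never match an SV call; drop them while
        # keeping calls and normalized variants aligned.
        caller_calls: list[StructuralVariantCall] = []
        caller_variants: list[NormalizedVariant | None] = []
        for v in caller_indels:
            size = len(v.alt) - len(v.ref)
            if size == 0:
                continue
            seq = None
            if size > 0 and v.alt.startswith(v.ref):
                seq = v.alt[len(v.ref):]
            caller_calls.append(
                StructuralVariantCall(
                    "insertion" if size > 0 else "deletion",
                    v.chrom, v.pos, size, seq,
                )
            )
            caller_variants.append(v)
    else:
        caller_calls = list(caller_indels)  # type: ignore[arg-type]
        caller_variants = None

    ctx = _MatchContext(reference, policy, tolerance, size_ratio)
    if caller_variants is None:
        caller_variants = ctx.normalize(caller_calls)
    sv_variants = ctx.normalize(list(sv_calls))

    redundant: list[StructuralVariantCall] = []
    unique: list[StructuralVariantCall] = []
    flags: list[bool] = []
    for call, cv in zip(sv_calls, sv_variants):
        hit = ctx.any_match(call, cv, caller_calls, caller_variants)
        flags.append(hit)
        (redundant if hit else unique).append(call)

    bins = np.asarray(size_bins)
    by_size: dict[str, dict[str, list]] = {}
    for sv_type in ("deletion", "insertion"):
        sizes = np.array(
            [abs(c.size) for c in sv_calls if c.sv_type == sv_type], dtype=np.int64
        )
        hit = np.array(
            [f for c, f in zip(sv_calls, flags) if c.sv_type == sv_type], dtype=bool
        )
        idx = np.searchsorted(bins, sizes, side="left")
        fracs, totals = [], []
        for b in range(len(bins)):
            mask = idx == b
            totals.append(int(mask.sum()))
            fracs.append(float(hit[mask].mean()) if mask.any() else float("nan"))
        by_size[sv_type] = {"bin_upper": bins.tolist(), "n": totals, "frac_redundant": fracs}

    return {
        "redundant": redundant,
        "unique_to_sv": unique,
        "flags": flags,
        "by_size": by_size,
    }


def phase_against_parents(
    proband_calls: Sequence[StructuralVariantCall],
    father_calls: Sequence[StructuralVariantCall] | None,
    mother_calls: Sequence[StructuralVariantCall] | None,
    *,
    reference: Mapping[str, str] | None = None,
    policy: str = "exact",
    tolerance: int = defaults.SV_POSITION_TOLERANCE,
    size_ratio: float = defaults.SV_SIZE_RATIO,
) -> list[str]:
    """Phase each proband call: matched in exactly one parent's call set ->
    ``one_parent``; in both -> ``both_parents``; in neither -> ``unassigned``.

    With a missing parental call set phasing is unavailable and every call
    is ``unassigned``.
    """
    if father_calls is None or mother_calls is None:
        return ["unassigned"] * len(proband_calls)
    ctx = _MatchContext(reference, policy, tolerance, size_ratio)
    fv = ctx.normalize(list(father_calls))
    mv = ctx.normalize(list(mother_calls))
    pv = ctx.normalize(list(proband_calls))
    phases = []
    for call, cv in zip(proband_calls, pv):
        in_f = ctx.any_match(call, cv, list(father_calls), fv)
        in_m = ctx.any_match(call, cv, list(mother_calls), mv)
        if in_f and in_m:
            phases.append("both_parents")
        elif in_f or in_m:
            phases.append("one_parent")
        else:
            phases.append("unassigned")
    return phases


def sv_founder_rarity(
    call: StructuralVariantCall,
    parental_call_sets: Mapping[str, Sequence[StructuralVariantCall]],
    pedigrees: Sequence[Pedigree],
    excluded_family: str,
    *,
    reference: Mapping[str, str] | None = None,
    policy: str = "exact",
    tolerance: int = defaults.SV_POSITION_TOLERANCE,
    size_ratio: float = defaults.SV_SIZE_RATIO,
    chrom_class: str = "autosomal",
    **rarity_kwargs,
) -> str:
    """Rarity of one SV call in the founder cohort.

    Every matched parental call contributes one alternate allele (the
    all-heterozygous assumption); ``n`` follows the founder chromosome
    count with the proband's own parents excluded.
    """
    ctx = _MatchContext(reference, policy, tolerance, size_ratio)
    (cv,) = ctx.normalize([call])
    founders = [
        f
        for ped in pedigrees
        if ped.family_id != excluded_family
        for f in ped.founders
    ]
    k = 0
    for f in founders:
        fc = list(parental_call_sets.get(f.id, ()))
        if fc and ctx.any_match(call, cv, fc, ctx.normalize(fc)):
            k += 1
    n = expected_allele_count(founders, chrom_class)
    return founder_frequency(k, n, chrom_class, **rarity_kwargs).rarity


def indel_funnel(
    proband_calls: Sequence[StructuralVariantCall],
    caller_indels: Sequence[StructuralVariantCall] | Sequence[NormalizedVariant],
    parental_call_sets: Mapping[str, Sequence[StructuralVariantCall]],
    pedigrees: Sequence[Pedigree],
    family_id: str,
    targets: Sequence[GenomicInterval],
    *,
    reference: Mapping[str, str] | None = None,
    policy: str = "exact",
    flank: int = defaults.TARGET_FLANK,
    tolerance: int = defaults.SV_POSITION_TOLERANCE,
    size_ratio: float = defaults.SV_SIZE_RATIO,
    **rarity_kwargs,
) -> dict:
    """Staged medium-indel funnel for one proband plus phase breakdowns.

    Stages: all calls; unique to the SV caller; rare/absent in founders;
    within target + flank.  Phase distributions are reported for (a) all
    calls and (b) the unique-and-rare subset.
    """
    ped = next(p for p in pedigrees if p.family_id == family_id)
    parents = ped.parents_of(ped.proband_id)
    father = next((p for p in parents if p.sex == "male"), None)
    mother = next((p for p in parents if p.sex == "female"), None)
    match_kw = dict(
        reference=reference, policy=policy, tolerance=tolerance, size_ratio=size_ratio
    )

    part = match_calls(proband_calls, caller_indels, **match_kw)
    unique = part["unique_to_sv"]

    rare_unique = [
        c
        for c in unique
        if sv_founder_rarity(
            c, parental_call_sets, pedigrees, family_id, **match_kw, **rarity_kwargs
        )
        in ("absent", "rare")
    ]
    in_target = [c for c in rare_unique if classify_target(c, targets, flank)]

    stages = FunnelReport(
        [
            FunnelStage("all_sv_calls", "all split-read calls", len(proband_calls)),
            FunnelStage("unique_to_sv", "not redundant with the genotype caller", len(unique)),
            FunnelStage("rare_or_absent", "founder rarity in {absent, rare}", len(rare_unique)),
            FunnelStage("in_target_flank", f"within target +/- {flank} bases", len(in_target)),
        ]
    )

    def phase_breakdown(calls: Sequence[StructuralVariantCall]) -> dict[str, int]:
        phases = phase_against_parents(
            calls,
            list(parental_call_sets.get(father.id, ())) if father else None,
            list(parental_call_sets.get(mother.id, ())) if mother else None,
            **match_kw,
        )
        return {
            p: phases.count(p) for p in ("one_parent", "both_parents", "unassigned")
        }

    return {
        "funnel": stages,
        "phase_all": phase_breakdown(list(proband_calls)),
        "phase_unique_rare": phase_breakdown(rare_unique),
        "unique_rare_calls": rare_unique,
        "in_target_calls": in_target,
    }
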