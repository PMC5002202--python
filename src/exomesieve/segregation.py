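"""Variant filtration under Mendelian disease models.

Variants surviving the transcript-effect and founder-rarity gates are tested
for consistency with four inheritance models — homozygous recessive,
compound heterozygous, X-linked and de novo dominant — over a configurable
subset of family members.  Constraints that reference excluded members are
vacuously satisfied, which is what makes a singleton analysis a superset of
a trio analysis of the same family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import defaults
from .core import GenotypeCall, NormalizedVariant, chromosome_class
from .founders import FounderFrequency, Pedigree

__all__ = [
    "EffectAnnotation",
    "CandidateCall",
    "FamilyConfiguration",
    "InvalidModelError",
    "MODELS",
    "effect_filter",
    "model_check",
    "run_filtration",
    "family_ablation",
]

MODELS = ("hom_recessive", "compound_het", "x_linked", "de_novo_dominant")

EFFECT_CLASSES = (
    "non_synonymous",
    "start_gain_loss",
    "stop_gain_loss",
    "frameshift",
    "canonical_splice",
    "intronic_near_splice",
    "other",
)

_CONFIG_LABELS = {1: "singleton", 3: "trio", 4: "quartet", 5: "quintet", 6: "sextet"}


class InvalidModelError(ValueError):
    """Model applied to an incompatible chromosome (x_linked on autosome)."""


@dataclass(frozen=True)
class EffectAnnotation:
    key: tuple[str, int, str, str]
    gene: str
    effect_class: str
    splice_distance: int | None = None

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        if self.effect_class == "intronic_near_splice" and (
            self.splice_distance is None or self.splice_distance < 1
        ):
            raise ValueError("intronic_near_splice needs splice_distance >= 1")


@dataclass(frozen=True)
class CandidateCall:
    """A variant (or compound-het pair) consistent with a disease model."""

    variants: tuple[NormalizedVariant, ...]
    model: str
    family_id: str
    configuration: str
    gene: str = ""
    genotype_summary: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "compound_het":
            if len(self.variants) != 2 or self.variants[0] == self.variants[1]:
                raise ValueError("compound_het needs two distinct variants")
        elif len(self.variants) != 1:
            raise ValueError(f"{self.model} takes exactly one variant")


@dataclass(frozen=True)
class FamilyConfiguration:
    """The subset of family members included in one analysis pass."""

    included: frozenset[str]
    label: str

    @classmethod
    def from_members(
        cls, pedigree: Pedigree, included: Iterable[str]
    ) -> "FamilyConfiguration":
        inc = frozenset(included)
        unknown = inc - {m.id for m in pedigree.members}
        if unknown:
            raise ValueError(f"members not in family: {sorted(unknown)}")
        if pedigree.proband_id not in inc:
            raise ValueError("configuration must include the proband")
        parents = {p.id for p in pedigree.parents_of(pedigree.proband_id)}
        if parents and 0 < len(parents & inc) < len(parents):
            raise ValueError("parents must be included together or not at all")
        return cls(inc, _CONFIG_LABELS.get(len(inc), f"members_{len(inc)}"))


def standard_ladder(pedigree: Pedigree) -> list[FamilyConfiguration]:
    """Nested singleton -> trio -> quartet -> ... ladder for one family."""
    proband = pedigree.proband
    parents = [p.id for p in pedigree.parents_of(proband.id)]
    sibs = [s.id for s in pedigree.siblings_of(proband.id)]
    ladder = [FamilyConfiguration.from_members(pedigree, [proband.id])]
    cur = [proband.id]
    if parents:
        cur = cur + parents
        ladder.append(FamilyConfiguration.from_members(pedigree, cur))
    for s in sibs:
        cur = cur + [s]
        ladder.append(FamilyConfiguration.from_members(pedigree, cur))
    return ladder


def effect_filter(
    annotations: Iterable[EffectAnnotation],
    allowed: Iterable[str] = defaults.EFFECT_CLASSES_KEPT,
    max_splice_distance: int = defaults.MAX_SPLICE_DISTANCE,
) -> set[tuple[str, int, str, str]]:
    """Keys of variants with at least one qualifying annotation.

    Intronic annotations qualify only within ``max_splice_distance`` bases
    of a splice site.
    """
    allowed = set(allowed)
    keep: set[tuple[str, int, str, str]] = set()
    for ann in annotations:
        if ann.effect_class not in allowed:
            continue
        if ann.effect_class == "intronic_near_splice":
            if ann.splice_distance is None or ann.splice_distance > max_splice_distance:
                continue
        keep.add(ann.key)
    return keep


def _pred(
    call: GenotypeCall | None,
    predicate,
    missing_policy: str,
) -> bool:
    """Evaluate one genotype constraint under the missing-data policy."""
    if call is None or call.missing:
        return missing_policy == "permissive"
    return predicate(call.alt_count, call.ploidy)


def model_check(
    variants: NormalizedVariant | Sequence[NormalizedVariant],
    model: str,
    pedigree: Pedigree,
    configuration: FamilyConfiguration,
    calls: Mapping[str, GenotypeCall] | Sequence[Mapping[str, GenotypeCall]],
    *,
    missing_policy: str = "conservative",
    chrom_name_map: Mapping[str, str] | None = None,
) -> bool:
    """True iff the included members' genotypes are consistent with ``model``.

    ``calls`` maps member id to that member's call at the variant; for
    ``compound_het`` pass two variants and two such mappings.  A missing call
    in an included member makes its constraint unsatisfied under the default
    conservative policy; ``missing_policy="permissive"`` treats it as
    vacuous.  Constraints on excluded members are always vacuous.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if missing_policy not in ("conservative", "permissive"):
        raise ValueError(f"bad missing policy {missing_policy!r}")

    if model == "compound_het":
        if not isinstance(variants, Sequence) or len(variants) != 2:
            raise ValueError("compound_het needs a pair of variants")
        return _check_compound_het(
            variants, pedigree, configuration, calls, missing_policy
        )

    if isinstance(variants, Sequence) and not isinstance(variants, NormalizedVariant):
        (variant,) = variants
        (calls_v,) = (calls,) if isinstance(calls, Mapping) else (calls[0],)
    else:
        variant, calls_v = variants, calls

    cls = chromosome_class(variant.chrom, chrom_name_map)
    if model == "x_linked" and cls != "X":
        raise InvalidModelError(f"x_linked model on {cls} chromosome {variant.chrom}")

    inc = configuration.included
    proband = pedigree.proband
    parents = {p.sex: p for p in pedigree.parents_of(proband.id)}
    others = [
        m for m in pedigree.members if m.id != proband.id and m.id not in
        {p.id for p in parents.values()}
    ]

    def get(ind_id: str) -> GenotypeCall | None:
        return calls_v.get(ind_id)

    def ok(member, predicate) -> bool:
        if member is None or member.id not in inc:
            return True
        return _pred(get(member.id), predicate, missing_policy)

    father = parents.get("male")
    mother = parents.get("female")

    if model == "hom_recessive":
        checks = [ok(proband, lambda c, p: c == 2)]
        for par in (father, mother):
            checks.append(ok(par, lambda c, p: c == 1))
        for m in others:
            if m.affected == "affected":
                checks.append(ok(m, lambda c, p: c == 2))
            elif m.affected == "unaffected":
                checks.append(ok(m, lambda c, p: c < 2))
        return all(checks)

    if model == "de_novo_dominant":
        checks = [ok(proband, lambda c, p: c == 1)]
        for par in (father, mother):
            checks.append(ok(par, lambda c, p: c == 0))
        for m in others:
            if m.affected == "affected":
                checks.append(ok(m, lambda c, p: c >= 1))
            elif m.affected == "unaffected":
                checks.append(ok(m, lambda c, p: c == 0))
        return all(checks)

    if model == "x_linked":
        checks = []
        if proband.sex == "male":
            checks.append(ok(proband, lambda c, p: c >= 1 and c == p))
            checks.append(ok(mother, lambda c, p: c == 1))
            checks.append(ok(father, lambda c, p: c == 0))
        elif proband.sex == "female":
            # female X-linked recessive: homozygous-alt proband, carrier mother,
            # hemizygous-carrier father
            checks.append(ok(proband, lambda c, p: c == 2))
            checks.append(ok(mother, lambda c, p: c >= 1))
            checks.append(ok(father, lambda c, p: c == p))
        else:
            return False
        for m in others:
            if m.affected == "unaffected":
                if m.sex == "male":
                    checks.append(ok(m, lambda c, p: c == 0))
                else:
                    checks.append(ok(m, lambda c, p: c < 2))
            elif m.affected == "affected":
                checks.append(ok(m, lambda c, p: c == p if m.sex == "male" else c == 2))
        return all(checks)

    raise AssertionError("unreachable")


def _check_compound_het(
    variants: Sequence[NormalizedVariant],
    pedigree: Pedigree,
    configuration: FamilyConfiguration,
    calls: Sequence[Mapping[str, GenotypeCall]],
    missing_policy: str,
) -> bool:
    v1, v2 = variants
    if v1 == v2:
        return False
    c1, c2 = calls
    inc = configuration.included
    proband = pedigree.proband
    parent_list = pedigree.parents_of(proband.id)
    parents_included = len(parent_list) == 2 and all(
        p.id in inc for p in parent_list
    )

    def pred(calls_v, ind_id, predicate):
        return _pred(calls_v.get(ind_id), predicate, missing_policy)

    # proband heterozygous for both variants
    if not (
        pred(c1, proband.id, lambda c, p: c == 1)
        and pred(c2, proband.id, lambda c, p: c == 1)
    ):
        return False

    # no included unaffected member carries both variants
    for m in pedigree.members:
        if m.id == proband.id or m.id not in inc or m.affected != "unaffected":
            continue
        carries1 = not pred(c1, m.id, lambda c, p: c == 0)
        carries2 = not pred(c2, m.id, lambda c, p: c == 0)
        if carries1 and carries2:
            return False

    # included affected siblings share both heterozygous variants
    for m in pedigree.siblings_of(proband.id):
        if m.id in inc and m.affected == "affected":
            if not (
                pred(c1, m.id, lambda c, p: c == 1)
                and pred(c2, m.id, lambda c, p: c == 1)
            ):
                return False

    # opposite parental origin, decidable only with both parents included
    if parents_included:
        def origins(calls_v):
            out = set()
            for p in parent_list:
                if pred(calls_v, p.id, lambda c, pl: c >= 1):
                    out.add(p.id)
            return out

        o1, o2 = origins(c1), origins(c2)
        if not any(a != b for a in o1 for b in o2):
            return False
    return True


def run_filtration(
    cohort,
    pedigree: Pedigree,
    configuration: FamilyConfiguration,
    founder_freqs: Mapping[tuple[str, int, str, str], FounderFrequency],
    annotations: Iterable[EffectAnnotation],
    *,
    allowed_effects: Iterable[str] = defaults.EFFECT_CLASSES_KEPT,
    max_splice_distance: int = defaults.MAX_SPLICE_DISTANCE,
    models: Sequence[str] = MODELS,
    missing_policy: str = "conservative",
    chrom_name_map: Mapping[str, str] | None = None,
) -> list[CandidateCall]:
    """Full per-family filtration: effect gate, rarity gate, model checks.

    ``founder_freqs`` must have been computed with this family excluded.
    Returns one :class:`CandidateCall` per (variant, satisfied model), plus
    one per qualifying compound-het pair.
    """
    annotations = list(annotations)
    effect_keys = effect_filter(annotations, allowed_effects, max_splice_distance)
    gene_of = {a.key: a.gene for a in annotations}

    surviving: list[NormalizedVariant] = []
    for v in cohort.variants:
        if v.key not in effect_keys:
            continue
        freq = founder_freqs.get(v.key)
        if freq is None or freq.rarity == "common":
            continue
        surviving.append(v)

    inc = configuration.included
    proband_id = pedigree.proband_id
    candidates: list[CandidateCall] = []
    single_models = [m for m in models if m != "compound_het"]

    calls_cache: dict[tuple[str, int, str, str], dict[str, GenotypeCall]] = {}

    def calls_for(v: NormalizedVariant) -> dict[str, GenotypeCall]:
        if v.key not in calls_cache:
            calls_cache[v.key] = {
                mid: cohort.call(v, mid) for mid in inc
            }
        return calls_cache[v.key]

    for v in surviving:
        cls = chromosome_class(v.chrom, chrom_name_map)
        cv = calls_for(v)
        for model in single_models:
            if model == "x_linked" and cls != "X":
                continue
            if model_check(
                v, model, pedigree, configuration, cv,
                missing_policy=missing_policy, chrom_name_map=chrom_name_map,
            ):
                candidates.append(
                    CandidateCall(
                        (v,), model, pedigree.family_id, configuration.label,
                        gene=gene_of.get(v.key, ""),
                        genotype_summary=tuple(
                            sorted((s, c.alt_count) for s, c in cv.items() if not c.missing)
                        ),
                    )
                )

    if "compound_het" in models:
        by_gene: dict[str, list[NormalizedVariant]] = {}
        for v in surviving:
            if _pred(calls_for(v).get(proband_id), lambda c, p: c == 1, "conservative"):
                by_gene.setdefault(gene_of.get(v.key, ""), []).append(v)
        for gene, vs in sorted(by_gene.items()):
            if not gene:
                continue
            for i in range(len(vs)):
                for j in range(i + 1, len(vs)):
                    v1, v2 = vs[i], vs[j]
                    if model_check(
                        (v1, v2), "compound_het", pedigree, configuration,
                        (calls_for(v1), calls_for(v2)),
                        missing_policy=missing_policy,
                        chrom_name_map=chrom_name_map,
                    ):
                        candidates.append(
                            CandidateCall(
                                (v1, v2), "compound_het", pedigree.family_id,
                                configuration.label, gene=gene,
                            )
                        )
    return candidates


def candidate_variant_count(candidates: Iterable[CandidateCall]) -> int:
    """Distinct variants appearing in any candidate (pairs contribute two)."""
    return len({v.key for c in candidates for v in c.variants})


def family_ablation(
    cohort,
    pedigree: Pedigree,
    ladder: Sequence[FamilyConfiguration],
    founder_freqs: Mapping[tuple[str, int, str, str], FounderFrequency],
    annotations: Iterable[EffectAnnotation],
    **kwargs,
) -> list[tuple[str, int]]:
    """Candidate-variant counts along a nested ladder of configurations.

    The ladder must be ordered by inclusion (each configuration's members a
    superset of the previous); counts are then non-increasing because added
    members only add constraints.
    """
    annotations = list(annotations)
    for prev, nxt in zip(ladder, ladder[1:]):
        if not prev.included <= nxt.included:
            raise ValueError(
                f"ladder not nested: {sorted(prev.included)} !<= {sorted(nxt.included)}"
            )
    out = []
    for config in ladder:
        cands = run_filtration(
            cohort, pedigree, config, founder_freqs, annotations, **kwargs
        )
        out.append((config.label, candidate_variant_count(cands)))
    return out
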