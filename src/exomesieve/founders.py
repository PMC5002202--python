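"""Pedigrees, founder-cohort allele counting and rarity classification.

The unaffected parents across all study families form an internal control
("founder") population.  When assessing a proband's variants that proband's
own parents are excluded, leaving an independent set of chromosomes from
which a minor allele frequency and its Wilson score interval are estimated.
A variant is then classed ``absent`` / ``rare`` / ``common``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from . import defaults
from .core import NormalizedVariant, chromosome_class

__all__ = [
    "Individual",
    "Pedigree",
    "FounderFrequency",
    "SexRequiredError",
    "expected_allele_count",
    "count_founder_alleles",
    "wilson_interval",
    "classify_rarity",
    "founder_frequency",
]


class SexRequiredError(ValueError):
    """X/Y allele counting needs a known sex for every founder."""


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str = "unknown"  # male | female | unknown
    affected: str = "unknown"  # affected | unaffected | unknown
    father_id: str | None = None
    mother_id: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"bad sex {self.sex!r}")
        if self.affected not in ("affected", "unaffected", "unknown"):
            raise ValueError(f"bad affected status {self.affected!r}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family: members in file order, exactly one designated proband."""

    family_id: str
    members: list[Individual]
    proband_id: str | None = None

    def __post_init__(self) -> None:
        ids = {m.id for m in self.members}
        if len(ids) != len(self.members):
            raise ValueError(f"duplicate member ids in family {self.family_id}")
        for m in self.members:
            for pid, want_sex in ((m.father_id, "male"), (m.mother_id, "female")):
                if pid is not None:
                    if pid not in ids:
                        raise ValueError(
                            f"{m.id}: parent {pid} not in family {self.family_id}"
                        )
                    parent = next(x for x in self.members if x.id == pid)
                    if parent.sex not in (want_sex, "unknown"):
                        raise ValueError(
                            f"{m.id}: parent {pid} has inconsistent sex"
                        )
        self._check_acyclic()
        if self.proband_id is None:
            affected = [m for m in self.members if m.affected == "affected"]
            if affected:
                self.proband_id = affected[0].id
        if self.proband_id is not None and self.proband_id not in ids:
            raise ValueError(
                f"proband {self.proband_id} not in family {self.family_id}"
            )

    def _check_acyclic(self) -> None:
        by_id = {m.id: m for m in self.members}
        for m in self.members:
            seen: set[str] = set()
            stack = [p for p in (m.father_id, m.mother_id) if p]
            while stack:
                cur = stack.pop()
                if cur == m.id:
                    raise ValueError(f"{m.id} is its own ancestor")
                if cur in seen or cur not in by_id:
                    continue
                seen.add(cur)
                a = by_id[cur]
                stack.extend(p for p in (a.father_id, a.mother_id) if p)

    def __iter__(self):
        return iter(self.members)

    def member(self, ind_id: str) -> Individual:
        for m in self.members:
            if m.id == ind_id:
                return m
        raise KeyError(ind_id)

    @property
    def proband(self) -> Individual:
        if self.proband_id is None:
            raise ValueError(f"family {self.family_id} has no proband")
        return self.member(self.proband_id)

    @property
    def founders(self) -> list[Individual]:
        """Members without recorded parents who are themselves parents."""
        parent_ids = {
            p for m in self.members for p in (m.father_id, m.mother_id) if p
        }
        return [m for m in self.members if m.is_founder and m.id in parent_ids]

    def parents_of(self, ind_id: str) -> list[Individual]:
        m = self.member(ind_id)
        return [self.member(p) for p in (m.father_id, m.mother_id) if p]

    def siblings_of(self, ind_id: str) -> list[Individual]:
        m = self.member(ind_id)
        return [
            s
            for s in self.members
            if s.id != ind_id
            and (s.father_id, s.mother_id) == (m.father_id, m.mother_id)
            and (s.father_id or s.mother_id)
        ]


@dataclass(frozen=True)
class FounderFrequency:
    """Founder-cohort allele frequency with its Wilson score interval."""

    k: int
    n: int
    maf: float
    ci_lower: float
    ci_upper: float
    rarity: str  # absent | rare | common

    def __post_init__(self) -> None:
        if self.k < 0 or self.n < 0 or self.k > self.n:
            raise ValueError(f"bad counts k={self.k}, n={self.n}")
        if self.n > 0 and not (
            -1e-12 <= self.ci_lower <= self.maf + 1e-12
            and self.maf - 1e-12 <= self.ci_upper <= 1 + 1e-12
        ):
            raise ValueError("interval does not bracket the point estimate")


def expected_allele_count(
    founders: Iterable[Individual], chrom_class: str
) -> int:
    """Chromosomes contributed by a founder set for one chromosome class.

    autosomal: 2 per founder; X: 2 per female + 1 per male; Y: 1 per male.
    """
    n = 0
    for f in founders:
        if chrom_class == "autosomal":
            n += 2
        elif chrom_class == "X":
            if f.sex == "unknown":
                raise SexRequiredError(f"founder {f.id}: sex needed for X")
            n += 2 if f.sex == "female" else 1
        elif chrom_class == "Y":
            if f.sex == "unknown":
                raise SexRequiredError(f"founder {f.id}: sex needed for Y")
            n += 1 if f.sex == "male" else 0
        else:
            raise ValueError(f"unknown chromosome class {chrom_class!r}")
    return n


def count_founder_alleles(
    variant: NormalizedVariant,
    genotypes: Mapping[str, "object"],
    pedigrees: Sequence[Pedigree],
    excluded_family: str | None = None,
    *,
    strict_missing: bool = False,
    chrom_name_map: Mapping[str, str] | None = None,
) -> tuple[int, int]:
    """Tally (k, n) alt/total founder alleles for one variant.

    ``genotypes`` maps sample id to an object with ``alt_count``, ``ploidy``
    and ``missing`` (a :class:`~exomesieve.core.GenotypeCall`); founders with
    no entry contribute reference alleles.  Explicitly missing calls are
    counted as homozygous reference by default (the absence rule extended to
    missing calls); ``strict_missing`` drops them from ``n`` instead.
    """
    family_ids = {p.family_id for p in pedigrees}
    if excluded_family is not None and excluded_family not in family_ids:
        raise KeyError(f"unknown family {excluded_family!r}")
    cls = chromosome_class(variant.chrom, chrom_name_map)
    k = n = 0
    for ped in pedigrees:
        if ped.family_id == excluded_family:
            continue
        for f in ped.founders:
            expected = expected_allele_count([f], cls)
            if expected == 0:
                continue
            call = genotypes.get(f.id)
            if call is None:
                n += expected
            elif getattr(call, "missing", False):
                if not strict_missing:
                    n += expected
            else:
                n += expected
                k += min(call.alt_count, expected)
    return k, n


def wilson_interval(
    k: int, n: int, confidence: float = defaults.WILSON_CONFIDENCE
) -> tuple[float, float, float]:
    """Point estimate and Wilson score interval for a binomial proportion.

    Inverts the score test: the interval is the set of p0 for which
    ``|p_hat - p0| / sqrt(p0 (1-p0)/n) <= z``.  Bounds are clamped to [0, 1].

    Returns ``(maf, ci_lower, ci_upper)``; raises on ``n == 0``.
    """
    if n <= 0:
        raise ValueError("frequency undefined for n = 0 counted alleles")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    z = norm.ppf(1 - (1 - confidence) / 2)
    p = k / n
    z2n = z * z / n
    denom = 1 + z2n
    center = (p + z2n / 2) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # analytically exact at the boundaries: k=0 -> lower 0, k=n -> upper 1
    lo = 0.0 if k == 0 else max(0.0, center - half)
    hi = 1.0 if k == n else min(1.0, center + half)
    return p, lo, hi


def classify_rarity(
    k: int,
    n: int,
    chrom_class: str = "autosomal",
    *,
    maf_threshold: float = defaults.RARITY_MAF_THRESHOLD,
    count_cutoffs: Mapping[str, int] | None = defaults.RARITY_COUNT_CUTOFFS,
    confidence: float = defaults.WILSON_CONFIDENCE,
) -> str:
    """Classify a founder allele count as absent / rare / common.

    With ``count_cutoffs`` configured (the default, reproducing the study's
    printed per-class rule) a variant is ``common`` when ``k`` reaches the
    cutoff for its chromosome class.  With ``count_cutoffs=None`` the pure
    interval rule applies instead: ``common`` when the Wilson lower bound
    exceeds ``maf_threshold``.  ``k == 0`` is always ``absent``.
    """
    if k == 0:
        return "absent"
    if count_cutoffs is not None:
        cutoff = count_cutoffs.get(chrom_class)
        if cutoff is None:
            raise KeyError(f"no count cutoff for class {chrom_class!r}")
        return "common" if k >= cutoff else "rare"
    _, lo, _ = wilson_interval(k, n, confidence)
    return "common" if lo > maf_threshold else "rare"


def cohort_founder_frequencies(
    cohort,
    pedigrees: Sequence[Pedigree],
    excluded_family: str | None = None,
    *,
    strict_missing: bool = False,
    chrom_name_map: Mapping[str, str] | None = None,
    **rarity_kwargs,
) -> dict[tuple[str, int, str, str], FounderFrequency]:
    """Founder (k, n), Wilson interval and rarity for every cohort variant.

    Vectorized equivalent of :func:`count_founder_alleles` applied to every
    variant of a :class:`~exomesieve.io.CohortGenotypes`-like object (any
    object with ``variants``, ``alt_counts`` and ``sample_index``).
    """
    family_ids = {p.family_id for p in pedigrees}
    if excluded_family is not None and excluded_family not in family_ids:
        raise KeyError(f"unknown family {excluded_family!r}")
    founders = [
        f
        for ped in pedigrees
        if ped.family_id != excluded_family
        for f in ped.founders
    ]
    result: dict[tuple[str, int, str, str], FounderFrequency] = {}
    if not founders:
        for v in cohort.variants:
            result[v.key] = founder_frequency(0, 0)
        return result
    cols = np.array([cohort.sample_index(f.id) for f in founders])
    counts = cohort.alt_counts[:, cols].astype(np.int64)
    missing = counts < 0
    classes = np.array(
        [chromosome_class(v.chrom, chrom_name_map) for v in cohort.variants]
    )
    for cls in ("autosomal", "X", "Y"):
        rows = np.nonzero(classes == cls)[0]
        if rows.size == 0:
            continue
        expected = np.array(
            [expected_allele_count([f], cls) for f in founders], dtype=np.int64
        )
        c = counts[rows]
        m = missing[rows]
        capped = np.minimum(np.where(m, 0, c), expected[None, :])
        k_rows = capped.sum(axis=1)
        if strict_missing:
            n_rows = np.where(m, 0, expected[None, :]).sum(axis=1)
        else:
            n_rows = np.full(rows.shape, int(expected.sum()), dtype=np.int64)
        for i, k, n in zip(rows, k_rows, n_rows):
            result[cohort.variants[i].key] = founder_frequency(
                int(k), int(n), cls, **rarity_kwargs
            )
    return result


def founder_frequency(
    k: int,
    n: int,
    chrom_class: str = "autosomal",
    **kwargs,
) -> FounderFrequency:
    """Bundle counts, Wilson interval and rarity class for one variant."""
    if n == 0:
        return FounderFrequency(k, n, float("nan"), float("nan"), float("nan"),
                                "absent" if k == 0 else "rare")
    maf, lo, hi = wilson_interval(k, n, kwargs.get("confidence", defaults.WILSON_CONFIDENCE))
    rarity = classify_rarity(k, n, chrom_class, **kwargs)
    return FounderFrequency(k, n, maf, lo, hi, rarity)
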