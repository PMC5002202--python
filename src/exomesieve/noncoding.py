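"""Prioritization of non-exonic variants.

Off-target and flanking capture yields a large set of variants outside exon
boundaries.  These are characterized by distance to the nearest exon,
filtered on founder-cohort rarity, and tiered by a genome-wide
deleteriousness score (raw + Phred-like scale): a negative raw score marks a
variant as indistinguishable from benign variation, Phred tiers 10/15/20
mark roughly the top 10%/3%/1% genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import defaults
from .core import GenomicInterval, merge_intervals
from .founders import FounderFrequency
from .report import FunnelReport, FunnelStage

__all__ = [
    "NoncodingVariant",
    "ExonDistanceIndex",
    "nearest_exon_distance",
    "distance_profile",
    "score_tier",
    "noncoding_funnel",
    "SCORE_TIERS",
]

SCORE_TIERS = ("benign_raw_negative", "low", "phred_ge_10", "phred_ge_15", "phred_ge_20")


@dataclass(frozen=True)
class NoncodingVariant:
    key: tuple[str, int, str, str]
    distance_to_exon: int
    frequency: FounderFrequency | None = None
    score_raw: float | None = None
    score_phred: float | None = None

    def __post_init__(self) -> None:
        if self.distance_to_exon < 1:
            raise ValueError("non-exonic variants have distance >= 1")
        if self.score_phred is not None and self.score_phred < 0:
            raise ValueError("Phred-scaled score must be >= 0")


class ExonDistanceIndex:
    """Nearest-exon distance queries over a merged exon interval set."""

    def __init__(self, exons: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in merge_intervals(exons):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        for chrom, tree in self._trees.items():
            ivs = sorted(tree)
            self._starts[chrom] = np.array([i.begin for i in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([i.end for i in ivs], dtype=np.int64)

    def distance(self, chrom: str, pos: int) -> tuple[int, bool]:
        """(distance in bases, exonic flag) for a 1-based position.

        Distance is 0 inside an exon; a position immediately adjacent to an
        exon boundary is at distance 1.  Raises KeyError when the chromosome
        carries no exons (distance undefined).
        """
        if chrom not in self._trees:
            raise KeyError(f"no exons on chromosome {chrom!r}")
        if self._trees[chrom].overlaps_point(pos - 1):
            return 0, True
        starts, ends = self._starts[chrom], self._ends[chrom]
        i = np.searchsorted(starts, pos - 1)
        best = np.iinfo(np.int64).max
        if i < len(starts):  # nearest exon to the right
            best = min(best, int(starts[i] - (pos - 1)))
        if i > 0:  # nearest exon to the left
            best = min(best, int(pos - ends[i - 1]))
        return best, False


def nearest_exon_distance(
    chrom: str, pos: int, exons: Iterable[GenomicInterval] | ExonDistanceIndex
) -> tuple[int, bool]:
    """Distance from a variant position to the nearest exon base."""
    index = exons if isinstance(exons, ExonDistanceIndex) else ExonDistanceIndex(exons)
    return index.distance(chrom, pos)


def distance_profile(
    distances: Sequence[int],
    bin_edges: Sequence[int] = (0, 100, 200, 300, 400, 500, 1000, 5000, 10**9),
    cutoff: int = defaults.NEAR_EXON_CUTOFF,
) -> dict:
    """Histogram of exon distances plus the cumulative fraction within
    ``cutoff`` bases; includes a log10(count) series per bin."""
    d = np.asarray(distances, dtype=np.int64)
    counts, edges = np.histogram(d, bins=np.asarray(bin_edges, dtype=np.int64))
    with np.errstate(divide="ignore"):
        log_counts = np.where(counts > 0, np.log10(np.maximum(counts, 1)), -np.inf)
    return {
        "bin_edges": list(map(int, edges)),
        "counts": counts.tolist(),
        "log10_counts": log_counts.tolist(),
        "n": int(d.size),
        "fraction_within_cutoff": float(np.mean(d <= cutoff)) if d.size else float("nan"),
        "median": float(np.median(d)) if d.size else float("nan"),
        "mean": float(d.mean()) if d.size else float("nan"),
    }


def score_tier(
    score_raw: float | None,
    score_phred: float | None,
    tiers: Sequence[float] = defaults.PHRED_TIERS,
) -> str:
    """Deleteriousness tier: negative raw score is benign regardless of the
    Phred value; otherwise the highest inclusive Phred threshold reached."""
    if score_raw is None or score_phred is None:
        return "unscored"
    if score_raw < 0:
        return "benign_raw_negative"
    best = "low"
    for t in sorted(tiers):
        if score_phred >= t:
            best = f"phred_ge_{int(t)}"
    return best


def noncoding_funnel(
    variants: Sequence[NoncodingVariant],
    tiers: Sequence[float] = defaults.PHRED_TIERS,
) -> FunnelReport:
    """The staged non-exonic prioritization funnel.

    Stages: all non-exonic variants; founder rarity in {absent, rare}; raw
    score not negative; then Phred >= 10 / 15 / 20.
    """
    stages = [FunnelStage("all_non_exonic", "distance_to_exon >= 1", len(variants))]
    current = list(variants)

    current = [
        v
        for v in current
        if v.frequency is not None and v.frequency.rarity in ("absent", "rare")
    ]
    stages.append(FunnelStage("rare_or_absent", "founder rarity in {absent, rare}", len(current)))

    current = [
        v for v in current if score_tier(v.score_raw, v.score_phred, tiers) not in
        ("benign_raw_negative", "unscored")
    ]
    stages.append(FunnelStage("not_benign", "raw score >= 0", len(current)))

    for t in sorted(tiers):
        current = [v for v in current if v.score_phred is not None and v.score_phred >= t]
        stages.append(FunnelStage(f"phred_ge_{int(t)}", f"Phred score >= {t}", len(current)))
    return FunnelReport(stages)
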