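"""Read-depth completeness analysis for exome capture.

Quantifies the potential false-negative space left by missing coverage:
per-position summaries over target/exon regions, per-exon minimum-depth
categories, first-exon and per-gene rollups, depth at known disease-variant
positions, and regions consistently under-covered in every sample.

Depth tracks are sparse: positions absent from the input have depth 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .core import GenomicInterval, merge_intervals

__all__ = [
    "DepthTrack",
    "ExonCoverageRecord",
    "BINS",
    "region_depth_summary",
    "bin_exons",
    "bin_proportions",
    "rollup",
    "known_position_depth",
    "cross_sample_consistency",
]

BINS = ("all_zero", "partial_zero", "min_1_9", "min_10_19", "min_ge_20")


class DepthTrack:
    """Per-chromosome sparse read-depth track (1-based positions)."""

    def __init__(self, per_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, depth) in per_chrom.items():
            pos = np.asarray(pos, dtype=np.int64)
            depth = np.asarray(depth, dtype=np.int64)
            if np.any(depth < 0):
                raise ValueError(f"negative depth on {chrom}")
            order = np.argsort(pos, kind="stable")
            pos, depth = pos[order], depth[order]
            if np.any(np.diff(pos) == 0):
                raise ValueError(f"duplicate positions on {chrom}")
            self._data[chrom] = (pos, depth)

    @classmethod
    def from_frames(cls, frames: Mapping[str, pd.DataFrame]) -> "DepthTrack":
        return cls(
            {c: (df["pos"].to_numpy(), df["depth"].to_numpy()) for c, df in frames.items()}
        )

    @classmethod
    def from_positions(cls, triples: Iterable[tuple[str, int, int]]) -> "DepthTrack":
        acc: dict[str, list[tuple[int, int]]] = {}
        for chrom, pos, depth in triples:
            acc.setdefault(chrom, []).append((pos, depth))
        return cls(
            {
                c: (np.array([p for p, _ in v]), np.array([d for _, d in v]))
                for c, v in acc.items()
            }
        )

    def depth_at(self, chrom: str, pos: int) -> int:
        if chrom not in self._data:
            return 0
        positions, depths = self._data[chrom]
        i = np.searchsorted(positions, pos)
        if i < len(positions) and positions[i] == pos:
            return int(depths[i])
        return 0

    def region_depths(self, interval: GenomicInterval) -> np.ndarray:
        """Dense per-base depths over a 0-based half-open interval."""
        length = len(interval)
        out = np.zeros(length, dtype=np.int64)
        if interval.chrom in self._data:
            positions, depths = self._data[interval.chrom]
            lo = np.searchsorted(positions, interval.start + 1)
            hi = np.searchsorted(positions, interval.end, side="right")
            idx = positions[lo:hi] - (interval.start + 1)
            out[idx] = depths[lo:hi]
        return out

    def region_min(self, interval: GenomicInterval) -> int:
        """Minimum depth over the interval, absent positions counting as 0."""
        if interval.chrom not in self._data:
            return 0
        positions, depths = self._data[interval.chrom]
        lo = np.searchsorted(positions, interval.start + 1)
        hi = np.searchsorted(positions, interval.end, side="right")
        covered = hi - lo
        if covered < len(interval):
            return 0
        return int(depths[lo:hi].min())


@dataclass(frozen=True)
class ExonCoverageRecord:
    exon: GenomicInterval
    min_depth: int
    has_zero: bool
    all_zero: bool
    bin: str

    def __post_init__(self) -> None:
        if self.bin not in BINS:
            raise ValueError(f"unknown bin {self.bin!r}")
        if self.all_zero and not self.has_zero:
            raise ValueError("all_zero implies has_zero")
        if self.has_zero and self.min_depth != 0:
            raise ValueError("has_zero implies min_depth == 0")


def _bin_of(min_depth: int, has_zero: bool, all_zero: bool) -> str:
    if all_zero:
        return "all_zero"
    if has_zero:
        return "partial_zero"
    if min_depth < 10:
        return "min_1_9"
    if min_depth < 20:
        return "min_10_19"
    return "min_ge_20"


def region_depth_summary(
    track: DepthTrack,
    regions: Sequence[GenomicInterval],
    thresholds: Sequence[int] = defaults.DEPTH_THRESHOLDS,
) -> dict:
    """Mean/median depth and fraction of positions at or above each threshold,
    over every base of the merged regions (absent positions are depth 0)."""
    if not regions:
        raise ValueError("regions must be non-empty")
    merged = merge_intervals(regions)
    depths = np.concatenate([track.region_depths(iv) for iv in merged])
    out = {
        "n_positions": int(depths.size),
        "mean": float(depths.mean()),
        "median": float(np.median(depths)),
    }
    for t in thresholds:
        out[f"frac_ge_{t}"] = float(np.mean(depths >= t))
    return out


def bin_exons(
    track: DepthTrack, exons: Sequence[GenomicInterval]
) -> list[ExonCoverageRecord]:
    """Per-exon minimum-depth records with the five coverage categories."""
    records = []
    for exon in exons:
        depths = track.region_depths(exon)
        mn = int(depths.min())
        all_zero = bool((depths == 0).all())
        has_zero = bool((depths == 0).any())
        records.append(
            ExonCoverageRecord(exon, mn, has_zero, all_zero, _bin_of(mn, has_zero, all_zero))
        )
    return records


def bin_proportions(records: Sequence[ExonCoverageRecord]) -> dict[str, float]:
    """Marginal bin proportions plus the cumulative low-coverage fractions
    ``min_lt_10`` (all-zero + partial-zero + min 1-9) and ``min_lt_20``."""
    n = len(records)
    if n == 0:
        return {b: 0.0 for b in BINS} | {"min_lt_10": 0.0, "min_lt_20": 0.0}
    marg = {b: sum(r.bin == b for r in records) / n for b in BINS}
    marg["min_lt_10"] = marg["all_zero"] + marg["partial_zero"] + marg["min_1_9"]
    marg["min_lt_20"] = marg["min_lt_10"] + marg["min_10_19"]
    return marg


def rollup(
    records: Sequence[ExonCoverageRecord], grouping: str
) -> dict[str, ExonCoverageRecord | list[ExonCoverageRecord]]:
    """Re-aggregate exon records by ``first_exons`` or by ``genes``.

    Gene minimum depth is the minimum over the gene's exons; the gene is
    all-zero only if every exon is, and has a zero if any exon does.
    """
    if grouping == "first_exons":
        return {"records": [r for r in records if r.exon.is_first_exon]}
    if grouping != "genes":
        raise ValueError(f"unknown grouping {grouping!r}")
    by_gene: dict[str, list[ExonCoverageRecord]] = {}
    for r in records:
        if not r.exon.label:
            raise ValueError(
                f"exon {r.exon.chrom}:{r.exon.start}-{r.exon.end} lacks a gene label"
            )
        by_gene.setdefault(r.exon.label, []).append(r)
    genes: dict[str, ExonCoverageRecord] = {}
    for gene, rs in by_gene.items():
        mn = min(r.min_depth for r in rs)
        all_zero = all(r.all_zero for r in rs)
        has_zero = any(r.has_zero for r in rs)
        span = GenomicInterval(
            rs[0].exon.chrom,
            min(r.exon.start for r in rs),
            max(r.exon.end for r in rs),
            gene,
        )
        genes[gene] = ExonCoverageRecord(
            span, mn, has_zero, all_zero, _bin_of(mn, has_zero, all_zero)
        )
    return {"records": list(genes.values()), "by_gene": genes}


def known_position_depth(
    track: DepthTrack,
    positions: Sequence[tuple[str, int, str]],
    thresholds: Sequence[int] = defaults.DEPTH_THRESHOLDS,
) -> dict:
    """Depth at known disease-variant positions (chrom, 1-based pos, gene).

    A gene counts as low at threshold t when at least one of its listed
    positions has depth < t.
    """
    rows = [
        {"chrom": c, "pos": p, "gene": g, "depth": track.depth_at(c, p)}
        for c, p, g in positions
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "gene", "depth"])
    out = {"per_position": df}
    for t in thresholds:
        out[f"frac_below_{t}"] = float((df["depth"] < t).mean()) if len(df) else 0.0
        low_genes = set(df.loc[df["depth"] < t, "gene"]) if len(df) else set()
        out[f"genes_low_{t}"] = sorted(low_genes)
        n_genes = df["gene"].nunique() if len(df) else 0
        out[f"gene_frac_low_{t}"] = len(low_genes) / n_genes if n_genes else 0.0
    return out


def _exon_id(iv: GenomicInterval) -> tuple[str, int, int, str]:
    return (iv.chrom, iv.start, iv.end, iv.label)


def cross_sample_consistency(
    per_sample_records: Mapping[str, Sequence[ExonCoverageRecord]],
    *,
    depth_threshold: int = defaults.LOW_DEPTH_THRESHOLD,
    gene_fraction: float = defaults.GENE_LOW_EXON_FRACTION,
    targets: Sequence[GenomicInterval] | None = None,
    containment: str = "overlap",
) -> dict:
    """Exons/genes under-covered in *every* sample.

    An exon is consistently low iff its minimum depth is below
    ``depth_threshold`` in all samples.  A gene qualifies when strictly more
    than ``gene_fraction`` of its exons are consistently low.  With
    ``targets`` given, the on-target subsets are reported under the chosen
    containment policy ("overlap": >=1 base overlaps a target; "full": the
    exon lies entirely within the merged targets).
    """
    samples = list(per_sample_records)
    if not samples:
        raise ValueError("no samples")
    exon_ids = [_exon_id(r.exon) for r in per_sample_records[samples[0]]]
    exon_by_id = {
        _exon_id(r.exon): r.exon for r in per_sample_records[samples[0]]
    }
    for s in samples[1:]:
        if [_exon_id(r.exon) for r in per_sample_records[s]] != exon_ids:
            raise ValueError(f"sample {s} has a mismatched exon model")

    low = np.ones(len(exon_ids), dtype=bool)
    for s in samples:
        low &= np.array(
            [r.min_depth < depth_threshold for r in per_sample_records[s]]
        )
    consistently_low = [exon_by_id[exon_ids[i]] for i in np.nonzero(low)[0]]

    exons_per_gene: dict[str, int] = {}
    low_per_gene: dict[str, int] = {}
    for i, eid in enumerate(exon_ids):
        gene = eid[3]
        exons_per_gene[gene] = exons_per_gene.get(gene, 0) + 1
        if low[i]:
            low_per_gene[gene] = low_per_gene.get(gene, 0) + 1
    genes_over_fraction = sorted(
        g
        for g, nlow in low_per_gene.items()
        if nlow / exons_per_gene[g] > gene_fraction
    )
    genes_all_low = sorted(
        g for g, nlow in low_per_gene.items() if nlow == exons_per_gene[g]
    )
    single_exon_all_low = sum(1 for g in genes_all_low if exons_per_gene[g] == 1)

    out = {
        "consistently_low_exons": consistently_low,
        "genes_over_fraction": genes_over_fraction,
        "genes_all_exons_low": genes_all_low,
        "n_single_exon_genes_all_low": single_exon_all_low,
    }
    if targets is not None:
        merged = merge_intervals(targets)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for t in merged:
            by_chrom.setdefault(t.chrom, []).append(t)

        def in_target(iv: GenomicInterval) -> bool:
            for t in by_chrom.get(iv.chrom, []):
                if containment == "overlap":
                    if iv.start < t.end and t.start < iv.end:
                        return True
                else:
                    if t.start <= iv.start and iv.end <= t.end:
                        return True
            return False

        on_target = [iv for iv in consistently_low if in_target(iv)]
        out["consistently_low_exons_in_target"] = on_target
        # genes over the fraction whose consistently-low exons are all on target
        low_exons_by_gene: dict[str, list[GenomicInterval]] = {}
        for iv in consistently_low:
            low_exons_by_gene.setdefault(iv.label, []).append(iv)
        out["genes_over_fraction_all_low_in_target"] = sorted(
            g
            for g in genes_over_fraction
            if all(in_target(iv) for iv in low_exons_by_gene.get(g, []))
        )
    return out
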