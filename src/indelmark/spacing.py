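"""Inter-marker spacing statistics and fine-mapping interval utilities.

Fine-mapping proceeds iteratively: pick a handful of evenly spaced
candidate markers inside the current mapping interval, genotype the
recombinant individuals, and shrink the interval to the region flanked
by the closest informative markers; repeat until a few candidate genes
remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import IndelRecord, PolymorphismTrack


@dataclass(frozen=True)
class GapSummary:
    n_markers: int
    mean_gap: float
    median_gap: float


@dataclass(frozen=True)
class SpacingStats:
    """Per-chromosome and pooled summaries of inter-polymorphism gaps.

    Gaps are successive position differences within one chromosome;
    chromosomes with fewer than two markers contribute none.  The
    aggregate pools all within-chromosome gaps (a single genome-wide
    average distance), rather than averaging per-chromosome means.
    """

    per_chrom: dict[str, GapSummary]
    aggregate: GapSummary


def spacing_stats(track: PolymorphismTrack) -> SpacingStats:
    """Mean/median inter-marker distance per chromosome and pooled."""
    per_chrom: dict[str, GapSummary] = {}
    pooled: list[np.ndarray] = []
    for chrom, records in track.by_chrom().items():
        if len(records) < 2:
            continue
        positions = np.array([r.pos for r in records], dtype=np.int64)
        gaps = np.diff(positions)
        per_chrom[chrom] = GapSummary(
            n_markers=len(records),
            mean_gap=float(gaps.mean()),
            median_gap=float(np.median(gaps)),
        )
        pooled.append(gaps)
    if not pooled:
        raise ValueError("no gaps defined: fewer than 2 markers on every chromosome")
    all_gaps = np.concatenate(pooled)
    aggregate = GapSummary(
        n_markers=len(track),
        mean_gap=float(all_gaps.mean()),
        median_gap=float(np.median(all_gaps)),
    )
    return SpacingStats(per_chrom=per_chrom, aggregate=aggregate)


@dataclass(frozen=True)
class MappingInterval:
    """A candidate region chrom:[start, end) with k markers requested."""

    chrom: str
    start: int
    end: int
    k: int = 5

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @classmethod
    def parse(cls, text: str, k: int = 5) -> "MappingInterval":
        """Parse 'chrom:start-end' (1-based inclusive, as users write it)."""
        chrom, _, span = text.partition(":")
        lo, _, hi = span.partition("-")
        if not (chrom and lo and hi):
            raise ValueError(f"cannot parse interval {text!r}; want chrom:start-end")
        return cls(chrom=chrom, start=int(lo.replace(",", "")) - 1,
                   end=int(hi.replace(",", "")), k=k)


def select_evenly_spaced(
    track: PolymorphismTrack, interval: MappingInterval
) -> list[IndelRecord]:
    """Pick up to k candidates closest to k evenly spaced interior anchors.

    Anchors sit at start + i*(end-start)/(k+1), i = 1..k, excluding the
    endpoints (flanking markers are typically genotyped already).  Each
    anchor takes its nearest unchosen in-interval candidate, lower
    coordinate winning ties.  If fewer than k candidates exist, all are
    returned.  Output is sorted by position.
    """
    candidates = [
        r
        for r in track.in_interval(interval.chrom, interval.start, interval.end)
        if r.contained_in(interval.start, interval.end)
    ]
    if not candidates:
        return []
    if len(candidates) <= interval.k:
        return sorted(candidates, key=IndelRecord.sort_key)
    span = interval.end - interval.start
    chosen: list[IndelRecord] = []
    for i in range(1, interval.k + 1):
        anchor = interval.start + i * span / (interval.k + 1)
        best = min(
            (r for r in candidates if r not in chosen),
            key=lambda r: (abs(r.ref_start - anchor), r.ref_start),
        )
        chosen.append(best)
    return sorted(chosen, key=IndelRecord.sort_key)


def refine_interval(
    interval: MappingInterval, recombinant_genotypes: dict[int, str]
) -> MappingInterval:
    """Shrink a mapping interval using per-marker genotyping calls.

    ``recombinant_genotypes`` maps a marker position (0-based reference)
    to the side of that marker on which the causal locus lies: "left" or
    "right".  The result is the smallest sub-interval consistent with
    every call; contradictory calls (locus right of marker A but left of
    a marker before A) raise, signalling an upstream genotyping error.
    """
    start, end = interval.start, interval.end
    for pos, side in recombinant_genotypes.items():
        if not (interval.start <= pos < interval.end):
            raise ValueError(f"marker at {pos} outside {interval}")
        if side == "right":
            start = max(start, pos)
        elif side == "left":
            end = min(end, pos)
        else:
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if start >= end:
        raise ValueError(
            f"contradictory genotypes: refined interval [{start}, {end}) is empty"
        )
    return MappingInterval(chrom=interval.chrom, start=start, end=end, k=interval.k)
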