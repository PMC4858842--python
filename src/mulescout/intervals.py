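"""Genomic intervals on the internal 0-based half-open convention.

Every coordinate inside the package is 0-based, half-open ``[start, end)``.
1-based inclusive conventions (GFF3, RepeatMasker, cytosine reports) are
converted at the I/O boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def distance_to(self, other: "GenomicInterval") -> int:
        """Closest-edge distance; 0 if overlapping; inf-like for other chrom."""
        if self.chrom != other.chrom:
            raise ValueError("distance between intervals on different chromosomes")
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end

    def expanded(self, flank: int, chrom_len: Optional[int] = None) -> "GenomicInterval":
        start = max(0, self.start - flank)
        end = self.end + flank if chrom_len is None else min(chrom_len, self.end + flank)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class AnnotatedInterval:
    """Interval plus feature metadata carried through from annotation files."""

    interval: GenomicInterval
    feature: str = "region"
    name: str = ""
    score: Optional[float] = None
    attributes: dict = field(default_factory=dict)


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome (strand ignored)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted((iv.start, iv.end) for iv in by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def union_length(ivs: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(ivs))


def clip_to(iv: GenomicInterval, frame: GenomicInterval) -> Optional[GenomicInterval]:
    """Intersect ``iv`` with ``frame``; None if disjoint."""
    if iv.chrom != frame.chrom:
        return None
    s, e = max(iv.start, frame.start), min(iv.end, frame.end)
    if s >= e:
        return None
    return GenomicInterval(iv.chrom, s, e, iv.strand)
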