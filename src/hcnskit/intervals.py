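"""Genomic intervals and interval-set utilities.

Every coordinate inside the package is 0-based, half-open, with an explicit
strand; conversions to and from 1-based or inclusive conventions happen only
at I/O boundaries (see :mod:`hcnskit.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from intervaltree import IntervalTree


@dataclass(frozen=True)
class GenomicInterval:
    """A located span on a named sequence.

    ``start`` is inclusive, ``end`` exclusive.  ``strand`` is ``'+'``,
    ``'-'`` or ``'.'`` (unspecified).  ``label`` is free-form (a feature
    name, gene id, element id, ...).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two spans share at least one base (bookended
        intervals do not overlap under the half-open convention)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return replace(
            self, start=max(self.start, other.start), end=min(self.end, other.end)
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance; 0 when the intervals overlap or touch."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across sequences")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start - other.end, other.start - self.end, 0)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals per sequence name.

    Strand and labels are dropped on merged output.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


class IntervalIndex:
    """Overlap index over a set of intervals, backed by one
    :class:`intervaltree.IntervalTree` per sequence name."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return sorted(
            (hit.data for hit in tree.overlap(iv.start, iv.end)),
            key=lambda g: (g.start, g.end),
        )

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return tree is not None and bool(tree.overlap(iv.start, iv.end))
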