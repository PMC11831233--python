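"""Stranded genomic intervals and the small interval algebra used to build
region classes.

Coordinates are 0-based half-open throughout (BED convention). GTF input is
converted on load; see :mod:`pacscope.annotation`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class Interval:
    """A stranded genomic interval, 0-based half-open.

    Attributes
    ----------
    chrom : str
        Sequence (chromosome) name.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must exceed ``start``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def _check_same_key(intervals: Sequence[Interval]) -> None:
    if not intervals:
        return
    chrom, strand = intervals[0].chrom, intervals[0].strand
    for iv in intervals:
        if iv.chrom != chrom or iv.strand != strand:
            raise ValueError(
                "intervals mix chromosomes or strands: "
                f"({chrom},{strand}) vs ({iv.chrom},{iv.strand})"
            )


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Return the minimal sorted disjoint cover of the union of ``intervals``.

    Touching intervals (``[0,10)`` and ``[10,20)``) are merged. All inputs
    must share one chromosome and strand.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    _check_same_key(ivs)
    if not ivs:
        return []
    out: list[Interval] = []
    cur_start, cur_end = ivs[0].start, ivs[0].end
    chrom, strand = ivs[0].chrom, ivs[0].strand
    for iv in ivs[1:]:
        if iv.start <= cur_end:  # overlap or touch
            cur_end = max(cur_end, iv.end)
        else:
            out.append(Interval(chrom, cur_start, cur_end, strand))
            cur_start, cur_end = iv.start, iv.end
    out.append(Interval(chrom, cur_start, cur_end, strand))
    return out


def _check_merged(intervals: Sequence[Interval], label: str) -> None:
    for prev, nxt in zip(intervals, intervals[1:]):
        if nxt.start < prev.end:
            raise ValueError(f"{label} intervals are not merged/disjoint")
        if nxt.start == prev.end:
            raise ValueError(f"{label} intervals touch; merge them first")


def subtract_intervals(
    a: Sequence[Interval], b: Sequence[Interval]
) -> list[Interval]:
    """Set difference ``a \\ b`` as disjoint intervals (bedtools-subtract
    semantics on one chromosome and strand).

    Both operands must already be merged (sorted, disjoint, non-touching);
    callers union first via :func:`merge_intervals`.
    """
    a = sorted(a, key=lambda iv: iv.start)
    b = sorted(b, key=lambda iv: iv.start)
    _check_same_key(list(a) + list(b))
    _check_merged(a, "minuend")
    _check_merged(b, "subtrahend")
    if not a:
        return []
    out: list[Interval] = []
    j = 0
    for iv in a:
        lo = iv.start
        while j < len(b) and b[j].end <= lo:
            j += 1
        k = j
        while k < len(b) and b[k].start < iv.end:
            blk = b[k]
            if blk.start > lo:
                out.append(Interval(iv.chrom, lo, blk.start, iv.strand))
            lo = max(lo, blk.end)
            if blk.end >= iv.end:
                break
            k += 1
        if lo < iv.end:
            out.append(Interval(iv.chrom, lo, iv.end, iv.strand))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in intervals)
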