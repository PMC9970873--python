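"""Genomic interval arithmetic on 0-based, half-open coordinates.

All internal coordinates are 0-based half-open ``[start, end)``; conversion
to and from 1-based systems happens only at VCF/GTF I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span.

    Parameters
    ----------
    chrom : str
        Contig name.
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        0-based exclusive end, ``> start``.
    strand : str
        ``'+'``, ``'-'`` or ``'.'`` (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"malformed interval: end {self.end} <= start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def pad(self, bases: int) -> "GenomicInterval":
        """Symmetrically extend by ``bases`` on each side (floored at 0)."""
        return GenomicInterval(self.chrom, max(0, self.start - bases), self.end + bases, self.strand)

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(|a∩b|/|a|, |a∩b|/|b|) — symmetric overlap fraction."""
        ov = self.overlap_length(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length, ov / other.length)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sort per chromosome and coalesce overlapping/abutting spans."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total merged bases covered (no double counting)."""
    return sum(iv.length for iv in merge_intervals(intervals))


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Pairwise intersection of two (merged) interval sets."""
    am, bm = merge_intervals(a), merge_intervals(b)
    out: list[GenomicInterval] = []
    for x in am:
        for y in bm:
            if x.chrom != y.chrom:
                continue
            s, e = max(x.start, y.start), min(x.end, y.end)
            if e > s:
                out.append(GenomicInterval(x.chrom, s, e))
    return sorted(out)


def pad_intervals(intervals: Iterable[GenomicInterval], bases: int) -> list[GenomicInterval]:
    return [iv.pad(bases) for iv in intervals]


def point_in_intervals(chrom: str, pos: int, intervals: Iterable[GenomicInterval]) -> bool:
    return any(iv.contains(chrom, pos) for iv in intervals)


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file (0-based half-open, as BED is natively)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 and row[5] in "+-" else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path, names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand if iv.strand != '.' else '+'}\n")
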