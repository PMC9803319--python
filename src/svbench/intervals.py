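"""Exact interval arithmetic on genomic coordinates.

All coordinates are 0-based half-open ``[start, end)``; conversion to/from the
1-based conventions of VCF and GFF3 happens only at I/O boundaries.  With this
convention ``length = end - start`` and the printed length of a span such as
IV:9,853,675-9,857,585 is the plain difference 3910 bp.

These primitives underpin truth-set placement (span budgets), reciprocal-overlap
classification of calls against truth, and the base-pair Jaccard index of two
callsets (intersection over union of covered base pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "GenomicInterval",
    "overlap_length",
    "reciprocal_overlap",
    "merged_span_length",
    "jaccard_index",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one sequence.

    Parameters
    ----------
    chrom
        Sequence (chromosome/contig) name.
    start
        0-based inclusive offset, ``0 <= start < end``.
    end
        0-based exclusive offset. Zero-length intervals are rejected.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise TypeError("start and end must be integers")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start (zero-length intervals rejected): "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:[{self.start},{self.end})"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs shared by two intervals.

    Returns 0 when the intervals lie on different sequences or are disjoint.
    Symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap fraction: ``min(ovl/len(a), ovl/len(b))`` in [0, 1].

    This is the "minimum reciprocal overlap" statistic used to decide whether a
    predicted variant matches a true one; it is 1.0 iff the intervals are
    identical and symmetric in its arguments.
    """
    ovl = overlap_length(a, b)
    if ovl == 0:
        return 0.0
    return min(ovl / a.length, ovl / b.length)


def _merge(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    """Union of intervals per chromosome as sorted disjoint (start, end) runs."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        runs: list[tuple[int, int]] = []
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:  # touching intervals do not merge coverage incorrectly:
                cur_e = max(cur_e, e)  # abutting runs cover the same bp set either way
            else:
                runs.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        runs.append((cur_s, cur_e))
        merged[chrom] = runs
    return merged


def merged_span_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total base pairs covered by the union of the intervals, over all chromosomes."""
    merged = _merge(intervals)
    return sum(e - s for runs in merged.values() for s, e in runs)


def _intersection_length(
    a: dict[str, list[tuple[int, int]]], b: dict[str, list[tuple[int, int]]]
) -> int:
    """bp intersection of two merged (disjoint, sorted) run dictionaries."""
    total = 0
    for chrom in a.keys() & b.keys():
        ra, rb = a[chrom], b[chrom]
        i = j = 0
        while i < len(ra) and j < len(rb):
            s = max(ra[i][0], rb[j][0])
            e = min(ra[i][1], rb[j][1])
            if e > s:
                total += e - s
            if ra[i][1] <= rb[j][1]:
                i += 1
            else:
                j += 1
    return total


def jaccard_index(
    set_a: Iterable[GenomicInterval], set_b: Iterable[GenomicInterval]
) -> float:
    """Base-pair Jaccard index of two interval collections.

    The number of base pairs in the intersection of the two coverage sets
    divided by the number in their union.  Overlapping intervals within one
    collection count once (coverage is a set of base pairs).  Both collections
    empty is defined as 0.0 for stable report aggregation.
    """
    ma = _merge(set_a)
    mb = _merge(set_b)
    len_a = sum(e - s for runs in ma.values() for s, e in runs)
    len_b = sum(e - s for runs in mb.values() for s, e in runs)
    inter = _intersection_length(ma, mb)
    union = len_a + len_b - inter
    if union == 0:
        return 0.0
    return inter / union
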