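"""Genome model and half-open interval algebra.

All coordinates in this package are 0-based, half-open (BED convention):
an interval [start, end) covers bases start .. end-1.  GFF3 input, which is
1-based inclusive, is converted on read (see :mod:`chipmeta.annotation`).

The operations here — merge, any-overlap flags, closest feature — are the
primitives behind consensus-peak building, co-occupancy percentages and
gene assignment.  They are deliberately small sorted-sweep implementations
whose behaviour is pinned down by brute-force oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


class CoordinateError(ValueError):
    """An interval lies outside the bounds of the bound genome assembly."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths: the coordinate universe.

    The declared chromosome order is authoritative for every sorted output
    produced by the package.
    """

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in assembly")
        for name, length in self.chroms:
            if not name:
                raise ValueError("empty chromosome name")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_index", {n: i for i, (n, _) in enumerate(self.chroms)})
        object.__setattr__(self, "_length", dict(self.chroms))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeAssembly":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._length

    def length(self, chrom: str) -> int:
        try:
            return self._length[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def order(self, chrom: str) -> int:
        """Rank of a chromosome in the declared order."""
        try:
            return self._index[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)

    def names(self) -> list[str]:
        return [n for n, _ in self.chroms]


@dataclass(frozen=True, order=True)
class GInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def shift(self, offset: int) -> "GInterval":
        return GInterval(self.chrom, self.start + offset, self.end + offset)


def validate_bounds(iv: GInterval, assembly: GenomeAssembly, what: str = "interval") -> None:
    """Raise CoordinateError naming the record if ``iv`` falls off the assembly."""
    if iv.chrom not in assembly:
        raise CoordinateError(f"{what} {iv.chrom}:[{iv.start},{iv.end}): unknown chromosome")
    if iv.end > assembly.length(iv.chrom):
        raise CoordinateError(
            f"{what} {iv.chrom}:[{iv.start},{iv.end}) exceeds chromosome "
            f"length {assembly.length(iv.chrom)}"
        )


def sort_key(assembly: GenomeAssembly | None):
    """Sort key (chromosome order, start, end); assembly order if bound."""
    if assembly is None:
        return lambda iv: (iv.chrom, iv.start, iv.end)
    return lambda iv: (assembly.order(iv.chrom), iv.start, iv.end)


def merge_intervals(
    intervals: Sequence[GInterval],
    min_gap: int = 0,
    assembly: GenomeAssembly | None = None,
) -> list[GInterval]:
    """Merge intervals into maximal disjoint intervals.

    Two intervals merge iff they are on the same chromosome and the gap
    between them is at most ``min_gap``; at the default ``min_gap=0``,
    touching intervals ([a,b) and [b,c)) merge.  Merging is transitive.
    Output is sorted by (chromosome order, start) and the operation is
    idempotent.

    Parameters
    ----------
    min_gap : int
        Maximum separation, in bp, for two intervals to be joined.
    assembly : GenomeAssembly, optional
        If given, every interval is bounds-checked against it and output
        follows its chromosome order.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    if assembly is not None:
        for iv in intervals:
            validate_bounds(iv, assembly)
    if not intervals:
        return []
    ivs = sorted(intervals, key=sort_key(assembly))
    out: list[GInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start - cur_end <= min_gap:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GInterval(cur_chrom, cur_start, cur_end))
    return out


def overlaps_any(
    queries: Sequence[GInterval],
    subjects: Sequence[GInterval],
) -> list[bool]:
    """Per-query flag: does the query share >= 1 bp with any subject?

    Half-open semantics: [0,100) and [100,200) do NOT overlap.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in subjects:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    # collapse subjects to disjoint runs per chromosome for a fast scan
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts: list[int] = []
        ends: list[int] = []
        for st, en in pairs:
            if ends and st < ends[-1]:
                ends[-1] = max(ends[-1], en)
            else:
                starts.append(st)
                ends.append(en)
        merged[chrom] = (starts, ends)

    import bisect

    flags: list[bool] = []
    for q in queries:
        run = merged.get(q.chrom)
        if run is None:
            flags.append(False)
            continue
        starts, ends = run
        i = bisect.bisect_right(starts, q.start)
        hit = False
        if i > 0 and ends[i - 1] > q.start:
            hit = True
        elif i < len(starts) and starts[i] < q.end:
            hit = True
        flags.append(hit)
    return flags


def closest_feature(
    chrom: str,
    pos: int,
    features: Sequence[GInterval],
    ids: Sequence[str] | None = None,
) -> tuple[int | None, int | None]:
    """Index and distance of the feature closest to a point.

    Distance is 0 if the point lies inside the feature, otherwise the
    distance to the nearer of the first base (start) and the last base
    (end-1).  Ties break on smaller distance first, then the
    lexicographically smallest feature identifier (``ids`` if supplied,
    else by (start, end, index)).  Returns (None, None) if no feature lies
    on the point's chromosome.
    """
    best: tuple | None = None
    best_idx: int | None = None
    best_dist: int | None = None
    for i, f in enumerate(features):
        if f.chrom != chrom:
            continue
        if f.start <= pos < f.end:
            d = 0
        else:
            d = min(abs(pos - f.start), abs(pos - (f.end - 1)))
        tie = ids[i] if ids is not None else (f.start, f.end, i)
        key = (d, tie)
        if best is None or key < best:
            best = key
            best_idx, best_dist = i, d
    return best_idx, best_dist
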