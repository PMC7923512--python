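"""Genomic interval sets for the conversion / studied / non-callable regions.

Intervals are 1-based and fully closed (the VCF position convention); BED
input, which is 0-based half-open, is shifted on read.  A :class:`RegionSet`
keeps, per contig, a sorted list of pairwise-disjoint, non-adjacent (merged)
intervals, so set operations are linear merges.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .contigs import normalize_contig


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed interval [start, end] on a canonical contig, 1-based."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


class RegionSet:
    """Canonical (sorted, merged) collection of genomic intervals."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
        self._by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, pairs in sorted(by_contig.items()):
            self._by_contig[contig] = _merge(pairs)

    # -- inspection --------------------------------------------------------

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self._by_contig)

    def intervals(self, contig: str | None = None) -> Iterator[GenomicInterval]:
        contigs = [contig] if contig is not None else list(self._by_contig)
        for c in contigs:
            for start, end in self._by_contig.get(c, []):
                yield GenomicInterval(c, start, end)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return self.intervals()

    def __bool__(self) -> bool:
        return bool(self._by_contig)

    def __len__(self) -> int:
        return sum(len(ivs) for ivs in self._by_contig.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._by_contig == other._by_contig

    def __repr__(self) -> str:
        parts = [f"{iv.contig}:{iv.start}-{iv.end}" for iv in self]
        return f"RegionSet({', '.join(parts)})"

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self)

    # -- algebra -----------------------------------------------------------

    def contains(self, contig: str, pos: int) -> bool:
        """True iff ``pos`` lies inside some interval on ``contig``."""
        pairs = self._by_contig.get(contig)
        if not pairs:
            return False
        i = bisect_right(pairs, (pos, float("inf"))) - 1
        return i >= 0 and pairs[i][0] <= pos <= pairs[i][1]

    def intersect(self, other: "RegionSet") -> "RegionSet":
        """Positions present in both sets."""
        out: list[GenomicInterval] = []
        for contig in self._by_contig:
            a = self._by_contig[contig]
            b = other._by_contig.get(contig)
            if not b:
                continue
            i = j = 0
            while i < len(a) and j < len(b):
                lo = max(a[i][0], b[j][0])
                hi = min(a[i][1], b[j][1])
                if lo <= hi:
                    out.append(GenomicInterval(contig, lo, hi))
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
        return RegionSet(out)


def _merge(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and coalesce overlapping or adjacent closed intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(pairs):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    return a.intersect(b)


def contains(rs: RegionSet, contig: str, pos: int) -> bool:
    return rs.contains(contig, pos)


def uncallable_within(
    conversion: RegionSet, studied: RegionSet, noncallable: RegionSet
) -> RegionSet:
    """Portions of the non-callable region inside both studied and conversion.

    A non-callable stretch only matters to the report where it was both
    requested (conversion) and actually examined (studied).
    """
    return noncallable.intersect(studied).intersect(conversion)


def read_regions(path: str | Path) -> RegionSet:
    """Read a BED file (3+ columns, 0-based half-open) into a RegionSet.

    Coordinates are shifted to the internal 1-based closed convention
    (start+1, end).  Contig names are normalized; lines on unrecognized
    contigs are ignored.  Extra columns, ``track``/``browser`` lines,
    comments and blank lines are tolerated.
    """
    intervals: list[GenomicInterval] = []
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                bed_start, bed_end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if bed_end <= bed_start or bed_start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid BED interval {bed_start}-{bed_end}"
                )
            contig = normalize_contig(fields[0])
            if contig is None:
                continue
            intervals.append(GenomicInterval(contig, bed_start + 1, bed_end))
    return RegionSet(intervals)
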