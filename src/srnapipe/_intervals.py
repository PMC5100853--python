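"""Interval containers for annotation layers.

Coordinates are 0-based half-open throughout; GFF3 (1-based closed) and
BED (0-based half-open) are converted at I/O boundaries only.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Iterator


@dataclass(frozen=True)
class Interval:
    contig: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty/negative interval {self.name}: [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, contig: str, start: int, end: int, strand: str | None = None) -> bool:
        if contig != self.contig:
            return False
        if strand is not None and strand != self.strand:
            return False
        return start < self.end and self.start < end

    def contains(self, contig: str, start: int, end: int, strand: str | None = None) -> bool:
        if contig != self.contig:
            return False
        if strand is not None and strand != self.strand:
            return False
        return self.start <= start and end <= self.end


class IntervalIndex:
    """Overlap queries against a static set of intervals.

    Per contig, intervals are kept sorted by start alongside a running
    maximum of ends, so a query scans only candidates that can overlap.
    """

    def __init__(self, intervals: Iterable[Interval]):
        self._by_contig: dict[str, tuple[list[int], list[Interval], list[int]]] = {}
        grouped: dict[str, list[Interval]] = {}
        for iv in intervals:
            grouped.setdefault(iv.contig, []).append(iv)
        for contig, ivs in grouped.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end, iv.name))
            starts = [iv.start for iv in ivs]
            maxend: list[int] = []
            running = 0
            for iv in ivs:
                running = max(running, iv.end)
                maxend.append(running)
            self._by_contig[contig] = (starts, ivs, maxend)

    def overlapping(
        self, contig: str, start: int, end: int, strand: str | None = None
    ) -> Iterator[Interval]:
        entry = self._by_contig.get(contig)
        if entry is None:
            return
        starts, ivs, maxend = entry
        hi = bisect.bisect_left(starts, end)  # candidates with start < end
        for i in range(hi - 1, -1, -1):
            if maxend[i] <= start:
                break  # nothing to the left can reach the query
            iv = ivs[i]
            if iv.end > start and (strand is None or iv.strand == strand):
                yield iv

    def any_overlap(self, contig: str, start: int, end: int, strand: str | None = None) -> bool:
        return next(self.overlapping(contig, start, end, strand), None) is not None
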