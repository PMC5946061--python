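"""Genome coordinate model, interval algebra, and BED/chrom.sizes I/O.

All coordinates are 0-based half-open (BED convention). Adjacent intervals
([0,100) vs [100,200)) share no base and therefore do not overlap.
Chromosome names are matched by exact string comparison; no "chr" aliasing.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "Interval",
    "ScoredInterval",
    "TagRecord",
    "read_chrom_sizes",
    "read_bed",
    "read_tags",
    "write_bed",
    "merge_intervals",
    "intersect_any",
]


class BedFormatError(ValueError):
    """A malformed line in a BED-like file, reported with its line number."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered map of chromosome name to length in bases.

    Iteration order is the insertion order of ``sizes`` and is stable, so
    every coordinate-ordered output of the pipeline is deterministic.
    """

    sizes: dict[str, int]

    def __post_init__(self) -> None:
        if not self.sizes:
            raise ValueError("layout must contain at least one chromosome")
        for name, length in self.sizes.items():
            if not isinstance(length, (int, np.integer)) or length < 1:
                raise ValueError(f"chromosome {name!r} has invalid length {length!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sizes)

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    @property
    def total_length(self) -> int:
        return sum(self.sizes.values())

    def chrom_order(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.sizes)}


@dataclass(frozen=True)
class Interval:
    """A genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def check_bounds(self, layout: GenomeLayout) -> None:
        if self.chrom not in layout:
            raise ValueError(f"chromosome {self.chrom!r} not in layout")
        if self.end > layout[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {layout[self.chrom]}"
            )


@dataclass(frozen=True)
class ScoredInterval(Interval):
    """Interval carrying a finite score and an optional label."""

    score: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.isfinite(self.score):
            raise ValueError(f"score must be finite, got {self.score!r}")


@dataclass(frozen=True)
class TagRecord(Interval):
    """The mapped footprint of one sequencing read; strand anchors its 5' end."""

    strand: str = "+"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """5' position: start on the + strand, end - 1 on the - strand."""
        return self.start if self.strand == "+" else self.end - 1


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column (name, length) chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise BedFormatError(f"{path}, line {lineno}: expected 2 columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise BedFormatError(
                    f"{path}, line {lineno}: non-integer length {fields[1]!r}"
                ) from None
            if name in sizes:
                raise BedFormatError(f"{path}, line {lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    return GenomeLayout(sizes)


def _parse_bed_fields(path, lineno: int, line: str) -> tuple[str, int, int, str, float, str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedFormatError(f"{path}, line {lineno}: expected >= 3 tab-separated columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise BedFormatError(f"{path}, line {lineno}: non-integer coordinates") from None
    if start < 0 or start >= end:
        raise BedFormatError(
            f"{path}, line {lineno}: invalid coordinates start={start} end={end}"
        )
    name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
    score = 0.0
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError:
            raise BedFormatError(f"{path}, line {lineno}: non-numeric score {fields[4]!r}") from None
    strand = "+"
    if len(fields) > 5 and fields[5] not in (".", ""):
        if fields[5] not in ("+", "-"):
            raise BedFormatError(f"{path}, line {lineno}: invalid strand {fields[5]!r}")
        strand = fields[5]
    return chrom, start, end, name, score, strand


def read_bed(path: str | Path, layout: GenomeLayout | None = None) -> list[ScoredInterval]:
    """Read a BED3/BED6 file into ScoredIntervals, preserving file order.

    Missing name/score columns default to ""/0.0. Malformed lines raise
    :class:`BedFormatError` naming the offending line number.
    """
    out: list[ScoredInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            chrom, start, end, name, score, _ = _parse_bed_fields(path, lineno, line)
            rec = ScoredInterval(chrom, start, end, score=score, name=name or None)
            if layout is not None:
                rec.check_bounds(layout)
            out.append(rec)
    return out


def read_tags(path: str | Path, layout: GenomeLayout | None = None) -> list[TagRecord]:
    """Read a BED6 tag file into TagRecords; strand defaults to '+' if absent."""
    out: list[TagRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            chrom, start, end, _, _, strand = _parse_bed_fields(path, lineno, line)
            rec = TagRecord(chrom, start, end, strand=strand)
            if layout is not None:
                rec.check_bounds(layout)
            out.append(rec)
    return out


def write_bed(records: Iterable[Interval], path: str | Path) -> None:
    """Write records as BED6 (name in col 4, score in col 5, strand in col 6)."""
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            name = getattr(rec, "name", None) or f"region_{i + 1}"
            score = getattr(rec, "score", 0.0)
            strand = getattr(rec, "strand", ".")
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{name}\t{score:g}\t{strand}\n")


def _sort_key(layout: GenomeLayout | None):
    if layout is None:
        return lambda iv: (iv.chrom, iv.start, iv.end)
    order = layout.chrom_order()
    return lambda iv: (order[iv.chrom], iv.start, iv.end)


def merge_intervals(
    intervals: Sequence[Interval],
    max_gap: int = 0,
    layout: GenomeLayout | None = None,
) -> list[Interval]:
    """Merge intervals whose gap is at most ``max_gap`` bases.

    Two intervals merge iff they overlap, touch, or are separated by a gap
    of <= max_gap bases on the same chromosome. The result is sorted and
    pairwise non-overlapping; merging is idempotent.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    if not intervals:
        return []
    ivs = sorted(intervals, key=_sort_key(layout))
    merged: list[Interval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start - cur_end <= max_gap:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(Interval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(Interval(cur_chrom, cur_start, cur_end))
    return merged


def is_merged(intervals: Sequence[Interval]) -> bool:
    """True iff the set is internally non-overlapping (order-insensitive)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in by_chrom.values():
        spans.sort()
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                return False
    return True


def intersect_any(
    queries: Sequence[Interval], subjects: Sequence[Interval]
) -> np.ndarray:
    """For each query, True iff it shares >= 1 bp with any subject interval.

    Half-open adjacency does not count as overlap. Runs in
    O((n + m) log m) via a per-chromosome sorted sweep and agrees with the
    quadratic all-pairs check.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in subjects:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    # collapse subjects so a binary search on starts suffices
    collapsed: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in spans:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        collapsed[chrom] = (starts, ends)
    hits = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        entry = collapsed.get(q.chrom)
        if entry is None:
            continue
        starts, ends = entry
        j = bisect.bisect_right(starts, q.end - 1) - 1  # last subject starting before q.end
        hits[i] = j >= 0 and ends[j] > q.start
    return hits
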