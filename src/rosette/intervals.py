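"""Genomic-interval data model, set algebra and peak-file I/O.

All coordinates are 0-based half-open (BED convention): an interval
``chrom:[start, end)`` covers ``end - start`` bases, and two intervals
that merely touch (``a.end == b.start``) share zero bases.  Chromosome
names are compared by exact string match; no "chr" normalization is
applied (see :func:`normalize_chrom_names` for an explicit opt-in).

Strand is carried through parsing and writing but ignored by every
overlap operation — peaks are unstranded; strand only matters for the
sign of TSS distances in :mod:`rosette.annotation`.
"""

from __future__ import annotations

import bisect
import operator
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "IntersectResult",
    "PeakParseError",
    "read_peaks",
    "write_bed",
    "overlaps",
    "overlap_length",
    "intersect_sets",
    "merge_adjacent",
    "cluster_intervals",
    "jaccard_bp",
    "normalize_chrom_names",
]

_VALID_STRANDS = {"+", "-", "."}


class PeakParseError(ValueError):
    """Raised when a peak file line cannot be parsed; names the line."""


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)`` with optional metadata."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        try:
            # accept any integral type (numpy ints included), store plain int
            object.__setattr__(self, "start", operator.index(self.start))
            object.__setattr__(self, "end", operator.index(self.end))
        except TypeError as exc:
            raise TypeError("start/end must be integers") from exc
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name or "")

    def __repr__(self) -> str:  # compact, log-friendly
        extra = f" {self.name}" if self.name else ""
        return f"<{self.chrom}:[{self.start},{self.end}){extra}>"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff the two intervals share at least ``min_bp`` bases.

    The default ``min_bp=1`` is the "overlapped by at least one base
    pair" rule used throughout peak-set comparisons.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be a positive integer")
    return overlap_length(a, b) >= min_bp


class IntervalSet:
    """An immutable, sorted collection of :class:`GenomicInterval`.

    Sorted by ``(chrom, start, end, name)`` on construction.  If a
    ``genome`` mapping of chromosome sizes is supplied, intervals must
    not extend past their chromosome.
    """

    __slots__ = ("_intervals", "genome")

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Mapping[str, int] | None = None,
    ) -> None:
        ivs = sorted(intervals, key=GenomicInterval.sort_key)
        if genome is not None:
            for iv in ivs:
                size = genome.get(iv.chrom)
                if size is None:
                    raise ValueError(f"chromosome {iv.chrom!r} absent from genome table")
                if iv.end > size:
                    raise ValueError(
                        f"interval {iv!r} extends past chromosome size {size}"
                    )
        self._intervals: tuple[GenomicInterval, ...] = tuple(ivs)
        self.genome = dict(genome) if genome is not None else None

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i):
        return self._intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals)"

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self._intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bases(self) -> int:
        """Covered bases counting overlaps once (per-base union size)."""
        return sum(len(iv) for iv in merge_adjacent(self, 0))


def _parse_bed_line(fields: list[str], lineno: int, fmt: str) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise PeakParseError(f"line {lineno}: non-integer coordinate") from exc
    if start >= end or start < 0:
        raise PeakParseError(
            f"line {lineno}: invalid coordinates start={start} end={end}"
        )
    name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else None
    score: float | None = None
    strand = "."
    if fmt == "narrowPeak":
        # ENCODE narrowPeak: score col 5, strand col 6, signalValue col 7
        strand = fields[5] if fields[5] in _VALID_STRANDS else "."
        try:
            score = float(fields[6])
        except ValueError as exc:
            raise PeakParseError(f"line {lineno}: bad signalValue {fields[6]!r}") from exc
    else:
        if len(fields) > 4 and fields[4] not in ("", "."):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise PeakParseError(f"line {lineno}: bad score {fields[4]!r}") from exc
        if len(fields) > 5 and fields[5] in _VALID_STRANDS:
            strand = fields[5]
    return GenomicInterval(fields[0], start, end, name=name, score=score, strand=strand)


def read_peaks(
    path: str | Path,
    format: str = "bed",
    genome: Mapping[str, int] | None = None,
) -> IntervalSet:
    """Read a BED3/BED5/BED6 or ENCODE narrowPeak file into an IntervalSet.

    Parameters
    ----------
    path:
        Tab-separated peak file, no header.  Lines starting with
        ``track``, ``browser`` or ``#`` are skipped.
    format:
        ``"bed"`` (3–6 columns; score from column 5) or
        ``"narrowPeak"`` (10 columns; score from the signalValue
        column 7, the MACS2 enrichment value).
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown format {format!r}: expected 'bed' or 'narrowPeak'")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PeakParseError(f"line {lineno}: fewer than 3 fields")
            if format == "narrowPeak" and len(fields) != 10:
                raise PeakParseError(
                    f"line {lineno}: narrowPeak requires 10 fields, got {len(fields)}"
                )
            intervals.append(_parse_bed_line(fields, lineno, format))
    return IntervalSet(intervals, genome=genome)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (sorted; missing name/score become ``.``/``0``)."""
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    with open(path, "w") as fh:
        for iv in ivs:
            # repr gives the shortest digits that round-trip the float exactly
            score = "0" if iv.score is None else repr(iv.score)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


@dataclass
class IntersectResult:
    """Pairing of two interval sets under the >=1 bp (or min_bp) overlap rule.

    Overlap counts are asymmetric: one a-interval may hit several
    b-intervals and vice versa, so both directions are reported.
    """

    pairs: list[tuple[GenomicInterval, GenomicInterval]]
    a_overlapping: int
    b_overlapping: int
    a_only: int
    b_only: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def intersect_sets(
    a: IntervalSet, b: IntervalSet, min_bp: int = 1
) -> IntersectResult:
    """All overlapping (a, b) interval pairs plus per-set overlap counts.

    Sorted sweep per chromosome; an interval counts as "overlapping"
    if at least one partner in the other set shares >= min_bp bases.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be a positive integer")
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    a_hit: set[int] = set()
    b_hit: set[int] = set()
    b_by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, iv in enumerate(b):
        b_by_chrom.setdefault(iv.chrom, []).append((j, iv))
    for chrom, blist in b_by_chrom.items():
        blist.sort(key=lambda t: t[1].start)
    for i, av in enumerate(a):
        blist = b_by_chrom.get(av.chrom)
        if not blist:
            continue
        starts = [t[1].start for t in blist]
        # rightmost b whose start could still overlap av
        hi = bisect.bisect_left(starts, av.end)
        for j, bv in blist[:hi]:
            if min(av.end, bv.end) - max(av.start, bv.start) >= min_bp:
                pairs.append((av, bv))
                a_hit.add(i)
                b_hit.add(j)
    return IntersectResult(
        pairs=pairs,
        a_overlapping=len(a_hit),
        b_overlapping=len(b_hit),
        a_only=len(a) - len(a_hit),
        b_only=len(b) - len(b_hit),
    )


def cluster_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int
) -> list[list[GenomicInterval]]:
    """Single-linkage clustering of intervals by gap threshold.

    Two same-chromosome intervals join a cluster when the gap between
    them (``next.start - running_end``) is <= ``max_gap``; clusters
    close transitively.  ``max_gap = -1`` therefore demands a strict
    >=1 bp overlap, ``max_gap = 0`` also joins book-ended intervals.
    This is the shared engine behind merging, stitching and
    replicate-consensus clustering.
    """
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    clusters: list[list[GenomicInterval]] = []
    current: list[GenomicInterval] = []
    cur_chrom: str | None = None
    cur_end = 0
    for iv in ivs:
        if current and iv.chrom == cur_chrom and iv.start - cur_end <= max_gap:
            current.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            if current:
                clusters.append(current)
            current = [iv]
            cur_chrom = iv.chrom
            cur_end = iv.end
    if current:
        clusters.append(current)
    return clusters


def merge_adjacent(
    intervals: IntervalSet | Sequence[GenomicInterval],
    max_gap: int,
    return_constituents: bool = False,
):
    """Merge intervals whose inter-region gap is <= ``max_gap``.

    The gap is ``next.start - prev.end``; 0 merges book-ended
    intervals, 12500 is the enhancer-stitching distance.  Merging is
    transitive: chains of small gaps collapse into one union span.

    Returns an :class:`IntervalSet` of union spans, or, when
    ``return_constituents`` is set, a list of
    ``(union_span, [constituent, ...])`` tuples in sorted order.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    clusters = cluster_intervals(list(intervals), max_gap)
    merged: list[GenomicInterval] = []
    out: list[tuple[GenomicInterval, list[GenomicInterval]]] = []
    for cluster in clusters:
        span = GenomicInterval(
            cluster[0].chrom,
            min(iv.start for iv in cluster),
            max(iv.end for iv in cluster),
        )
        merged.append(span)
        out.append((span, cluster))
    if return_constituents:
        return out
    return IntervalSet(merged)


def jaccard_bp(a: IntervalSet, b: IntervalSet) -> float:
    """Base-pair Jaccard index of two interval sets.

    Shared covered bases divided by union covered bases, after
    collapsing each set to its per-base union.  1.0 when both sets are
    empty.
    """
    ma = merge_adjacent(a, 0) if len(a) else IntervalSet()
    mb = merge_adjacent(b, 0) if len(b) else IntervalSet()
    inter = sum(
        overlap_length(x, y) for x, y in intersect_sets(ma, mb).pairs
    ) if len(ma) and len(mb) else 0
    union = ma.total_bases() + mb.total_bases() - inter
    return inter / union if union else 1.0


def normalize_chrom_names(iset: IntervalSet, prefix: str = "chr") -> IntervalSet:
    """Return a copy with the given prefix ensured on every chromosome name.

    Off by default everywhere; silent chr/no-chr aliasing corrupts
    overlap counts, so callers must opt in explicitly.
    """
    fixed = [
        iv if iv.chrom.startswith(prefix) else replace(iv, chrom=prefix + iv.chrom)
        for iv in iset
    ]
    return IntervalSet(fixed, genome=None)
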