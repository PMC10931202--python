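"""Super-enhancer calling: stitch, score, rank, slope-1 tangent cutoff.

The procedure follows the classic hockey-stick strategy: active
enhancers within 12.5 kb of one another are stitched into larger
regions; each stitched region is scored by its input-subtracted,
library-size-normalized H3K27ac signal (CPM in treatment minus CPM in
the control library); regions are sorted ascending by score; rank and
signal are both scaled to [0, 1]; and super-enhancers are the regions
past the point where a line of slope 1 is tangent to the scaled
rank-signal curve from below — geometrically, where the discrete slope
of the curve rises above 1.

Fragments are counted by midpoint membership: a fragment belongs to a
region iff its midpoint lies inside, which makes edge-spanning
fragments unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet, merge_adjacent

__all__ = [
    "SignalLibrary",
    "StitchedRegion",
    "stitch_enhancers",
    "score_region",
    "score_regions",
    "call_superenhancers",
    "hockey_stick_report",
    "DEFAULT_STITCH_BP",
]

logger = logging.getLogger(__name__)

DEFAULT_STITCH_BP = 12_500

#: absolute tie tolerance on the [0,1]-scaled rank-signal curve
_TIE_TOL = 1e-9


class SignalLibrary:
    """A sequenced-fragment library for signal scoring.

    Holds fragment spans (BED-style intervals) and the library size
    used for counts-per-million normalization.  ``library_size``
    defaults to the number of fragments; it may be set larger (e.g.
    total sequenced fragments when only a subset is loaded) but never
    smaller than any per-region count.
    """

    def __init__(self, fragments: IntervalSet, library_size: int | None = None):
        if library_size is None:
            library_size = len(fragments)
        if library_size <= 0:
            raise ValueError("library_size must be positive")
        if library_size < len(fragments):
            raise ValueError("library_size smaller than the fragment count")
        self.fragments = fragments
        self.library_size = library_size
        # sorted midpoint arrays per chromosome, for O(log n) region counts
        self._midpoints: dict[str, np.ndarray] = {}
        for chrom, ivs in fragments.by_chrom().items():
            self._midpoints[chrom] = np.sort(
                np.array([iv.center for iv in ivs], dtype=np.int64)
            )

    def count_in(self, region: GenomicInterval) -> int:
        """Fragments whose midpoint lies within the region (half-open)."""
        mids = self._midpoints.get(region.chrom)
        if mids is None:
            return 0
        lo = int(np.searchsorted(mids, region.start, side="left"))
        hi = int(np.searchsorted(mids, region.end, side="left"))
        return hi - lo

    def cpm_in(self, region: GenomicInterval) -> float:
        return self.count_in(region) / self.library_size * 1e6

    def __repr__(self) -> str:
        return f"SignalLibrary({len(self.fragments)} fragments, size {self.library_size})"


@dataclass
class StitchedRegion:
    """A merged enhancer cluster with its rank-signal bookkeeping."""

    interval: GenomicInterval
    constituents: list[GenomicInterval]
    signal_score: float = float("nan")
    rank: int | None = None  # ascending by score, 1..n
    scaled_rank: float | None = None
    scaled_signal: float | None = None
    is_super: bool = False

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


def stitch_enhancers(
    enhancers: IntervalSet, stitch_bp: int = DEFAULT_STITCH_BP
) -> list[StitchedRegion]:
    """Stitch enhancers within ``stitch_bp`` of each other into regions.

    Delegates to the generic gap-merge; singleton enhancers become
    single-constituent regions.  Empty input yields an empty list.
    """
    if stitch_bp < 0:
        raise ValueError("stitch_bp must be non-negative")
    if len(enhancers) == 0:
        return []
    out = []
    for span, members in merge_adjacent(enhancers, stitch_bp, return_constituents=True):
        out.append(StitchedRegion(interval=span, constituents=list(members)))
    return out


def score_region(
    region: StitchedRegion | GenomicInterval,
    treatment: SignalLibrary,
    control: SignalLibrary,
) -> float:
    """Input-subtracted CPM score of a region.

    score = CPM(treatment in region) - CPM(control in region).
    Negative scores (control exceeds treatment) are retained; they
    simply rank lowest.
    """
    iv = region.interval if isinstance(region, StitchedRegion) else region
    return treatment.cpm_in(iv) - control.cpm_in(iv)


def score_regions(
    regions: Sequence[StitchedRegion],
    treatment: SignalLibrary,
    control: SignalLibrary,
) -> list[StitchedRegion]:
    """Score each stitched region in place (and return the list)."""
    for r in regions:
        r.signal_score = score_region(r, treatment, control)
    return regions


def call_superenhancers(
    regions: Sequence[StitchedRegion],
) -> tuple[list[StitchedRegion], float | None]:
    """Flag super-enhancers at the slope-1 tangent of the ranked curve.

    Regions are sorted ascending by ``signal_score``; ranks are 1..n
    with ``scaled_rank = rank/n``.  Scores are shifted so the minimum
    is zero when negatives exist, then scaled by the maximum to give
    ``scaled_signal`` in [0, 1].  The cutoff is the point where a line
    of slope 1 touches the scaled curve from below, i.e. the index
    minimizing ``scaled_signal - scaled_rank``; ties resolve to the
    highest such rank so tied regions fall on the non-super side.
    Regions strictly above the cutoff rank AND strictly above the
    cutoff score are super (score ties with the cutoff are never
    super).

    Returns the regions sorted ascending by score, plus the cutoff
    signal score (None when no call was possible).
    """
    regions = sorted(regions, key=lambda r: (r.signal_score, r.interval.sort_key()))
    n = len(regions)
    for i, r in enumerate(regions, start=1):
        r.rank = i
        r.scaled_rank = i / n if n else None
        r.is_super = False
    if n < 2:
        if n:
            logger.warning("fewer than 2 regions: no super-enhancer call made")
            regions[0].scaled_signal = None
        return list(regions), None
    scores = np.array([r.signal_score for r in regions], dtype=float)
    shift = min(scores.min(), 0.0)
    shifted = scores - shift
    top = shifted.max()
    if top <= 0:
        logger.warning("all scores <= 0 after shift: no super-enhancers")
        for r in regions:
            r.scaled_signal = 0.0
        return list(regions), None
    y = shifted / top
    x = np.arange(1, n + 1) / n
    for r, yi in zip(regions, y):
        r.scaled_signal = float(yi)
    diff = y - x
    # tangent from below: minimal y - x; ties (within numerical noise of
    # the [0,1]-scaled curve) -> largest index, i.e. the non-super side
    tied = np.flatnonzero(diff <= diff.min() + _TIE_TOL)
    cutoff_idx = int(tied[-1])
    cutoff_score = float(scores[cutoff_idx])
    for r in regions:
        r.is_super = r.rank > cutoff_idx + 1 and r.signal_score > cutoff_score
    return list(regions), cutoff_score


def hockey_stick_report(
    regions: Sequence[StitchedRegion], cutoff_score: float | None = None
) -> dict:
    """Plot-ready rank/score table plus super vs typical counts.

    Expects :func:`call_superenhancers` to have been applied.  Returns
    a dict with keys ``table`` (list of per-region dicts ordered by
    rank), ``cutoff_score``, ``n_super`` and ``n_typical``.
    """
    ordered = sorted(regions, key=lambda r: (r.rank if r.rank is not None else 0))
    table = [
        {
            "rank": r.rank,
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "n_constituents": r.n_constituents,
            "signal_score": r.signal_score,
            "scaled_rank": r.scaled_rank,
            "scaled_signal": r.scaled_signal,
            "is_super": r.is_super,
        }
        for r in ordered
    ]
    n_super = sum(1 for r in ordered if r.is_super)
    return {
        "table": table,
        "cutoff_score": cutoff_score,
        "n_super": n_super,
        "n_typical": len(ordered) - n_super,
    }
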