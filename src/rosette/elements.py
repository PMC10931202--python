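"""Promoter/enhancer classification from histone-mark co-occurrence.

The operational rules, applied per candidate site:

* promoter — overlaps both an H3K4me3 peak and an H3K27ac peak;
* enhancer — overlaps H3K27ac and H3K4me1 peaks, does NOT overlap any
  H3K4me3 peak, and its center lies more than 1 kb from every TSS;
* unclassified — everything else (H3K4me1-only or H3K27ac-only sites
  get no invented class).

Mark presence is a binary >=1 bp overlap with that mark's (consensus)
peak set.  The two labels are mutually exclusive by construction:
H3K4me3 presence separates them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .annotation import GeneRecord, annotate_nearest_tss
from .intervals import GenomicInterval, IntervalSet, intersect_sets

__all__ = ["RegulatoryElement", "classify_elements", "active_enhancers"]

logger = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K4me1", "H3K27ac")


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    element_class: str  # promoter | enhancer | unclassified
    marks_present: frozenset[str]

    def __post_init__(self) -> None:
        if self.element_class not in ("promoter", "enhancer", "unclassified"):
            raise ValueError(f"bad element_class {self.element_class!r}")
        if not self.marks_present <= set(MARKS):
            raise ValueError(f"unknown marks {self.marks_present - set(MARKS)}")


def _hit_indices(candidates: IntervalSet, marks: IntervalSet) -> set[int]:
    hits: set[int] = set()
    index = {(iv.chrom, iv.start, iv.end, iv.name or ""): i for i, iv in enumerate(candidates)}
    for a, _ in intersect_sets(candidates, marks).pairs:
        hits.add(index[(a.chrom, a.start, a.end, a.name or "")])
    return hits


def classify_elements(
    candidate_sites: IntervalSet | None,
    h3k4me3: IntervalSet,
    h3k4me1: IntervalSet,
    h3k27ac: IntervalSet,
    genes: Sequence[GeneRecord],
    proximal_bp: int = 1000,
) -> list[RegulatoryElement]:
    """Classify candidate sites into promoters, enhancers, unclassified.

    ``candidate_sites`` defaults to the H3K27ac peak set (both rules
    require H3K27ac, so that set is the natural candidate universe).
    TSS distance is measured from the candidate center, consistent
    with :mod:`rosette.annotation`.
    """
    if candidate_sites is None:
        candidate_sites = h3k27ac
    if len(h3k27ac) == 0:
        logger.warning("empty H3K27ac set: no active elements detectable")
        return [
            RegulatoryElement(iv, "unclassified", frozenset())
            for iv in candidate_sites
        ]
    me3_hits = _hit_indices(candidate_sites, h3k4me3)
    me1_hits = _hit_indices(candidate_sites, h3k4me1)
    ac_hits = _hit_indices(candidate_sites, h3k27ac)
    annotated = annotate_nearest_tss(candidate_sites, list(genes))

    out: list[RegulatoryElement] = []
    for i, (iv, ann) in enumerate(zip(candidate_sites, annotated)):
        marks = set()
        if i in me3_hits:
            marks.add("H3K4me3")
        if i in me1_hits:
            marks.add("H3K4me1")
        if i in ac_hits:
            marks.add("H3K27ac")
        distal = ann.abs_distance > proximal_bp
        if "H3K4me3" in marks and "H3K27ac" in marks:
            cls = "promoter"
        elif (
            "H3K27ac" in marks
            and "H3K4me1" in marks
            and "H3K4me3" not in marks
            and distal
        ):
            cls = "enhancer"
        else:
            cls = "unclassified"
        out.append(RegulatoryElement(iv, cls, frozenset(marks)))
    return out


def active_enhancers(elements: Sequence[RegulatoryElement]) -> IntervalSet:
    """The enhancer-class intervals — input to super-enhancer stitching."""
    return IntervalSet(
        e.interval for e in elements if e.element_class == "enhancer"
    )
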