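"""Nearest-TSS assignment, distance binning, proximal/distal classification.

Distances run from the peak *center* (``floor((start+end)/2)``) to the
gene's transcription start site; the signed distance is
``center - tss`` flipped in sign on minus-strand genes, so positive
means downstream of the TSS in the gene's reading direction.  One TSS
per gene record — multi-isoform genes must be pre-flattened by the
caller.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "GeneRecord",
    "AnnotatedPeak",
    "annotate_nearest_tss",
    "bin_tss_distances",
    "classify_tss_proximity",
    "read_gene_table",
    "write_gene_table",
    "DEFAULT_DISTANCE_EDGES",
]

logger = logging.getLogger(__name__)

#: conventional log-decade bins: [0,1kb], (1kb,10kb], (10kb,100kb], >100kb
DEFAULT_DISTANCE_EDGES: tuple[int, ...] = (1_000, 10_000, 100_000)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak with its nearest gene and signed TSS distance.

    ``nearest_gene`` is None (and the distance infinite) for peaks on
    chromosomes without any gene.
    """

    interval: GenomicInterval
    nearest_gene: str | None
    signed_distance: float  # int bp, or math.inf when no gene available

    @property
    def abs_distance(self) -> float:
        return abs(self.signed_distance)


def annotate_nearest_tss(
    peaks: IntervalSet | Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
) -> list[AnnotatedPeak]:
    """Assign each peak the gene whose TSS is nearest its center.

    Nearest means minimum ``|center - tss|`` among same-chromosome
    genes; ties (equidistant TSSs, or several genes sharing one TSS)
    break to the lexicographically smallest gene_id.  Peaks on a
    chromosome with no genes get a null annotation with infinite
    distance and a logged warning.
    """
    if not genes:
        raise ValueError("at least one gene record required")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays: dict[str, tuple[np.ndarray, list[GeneRecord]]] = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: (g.tss, g.gene_id))
        arrays[chrom] = (np.array([g.tss for g in glist], dtype=np.int64), glist)

    out: list[AnnotatedPeak] = []
    warned: set[str] = set()
    for pk in peaks:
        entry = arrays.get(pk.chrom)
        if entry is None:
            if pk.chrom not in warned:
                logger.warning("no genes on chromosome %s; null annotation", pk.chrom)
                warned.add(pk.chrom)
            out.append(AnnotatedPeak(pk, None, math.inf))
            continue
        tss_arr, glist = entry
        center = pk.center
        j = int(np.searchsorted(tss_arr, center))
        # candidates: insertion neighbours, then widen over exact-distance ties
        best_d = None
        for k in (j - 1, j):
            if 0 <= k < len(glist):
                d = abs(center - int(tss_arr[k]))
                if best_d is None or d < best_d:
                    best_d = d
        assert best_d is not None
        tied: list[GeneRecord] = []
        k = j - 1
        while k >= 0 and abs(center - int(tss_arr[k])) == best_d:
            tied.append(glist[k])
            k -= 1
        k = j
        while k < len(glist) and abs(center - int(tss_arr[k])) == best_d:
            tied.append(glist[k])
            k += 1
        gene = min(tied, key=lambda g: g.gene_id)
        signed = center - gene.tss
        if gene.strand == "-":
            signed = -signed
        out.append(AnnotatedPeak(pk, gene.gene_id, signed))
    return out


def bin_tss_distances(
    annotated: Sequence[AnnotatedPeak],
    edges: Sequence[int] = DEFAULT_DISTANCE_EDGES,
) -> dict[str, float]:
    """Percent of peaks per absolute-distance bin.

    Edges must be strictly increasing positive thresholds; edges
    (1kb, 10kb, 100kb) yield bins [0,1kb], (1kb,10kb], (10kb,100kb]
    and >100kb.  Null-annotated peaks are excluded; percentages sum
    to 100 over the remainder.
    """
    edges = list(edges)
    if any(e <= 0 for e in edges) or any(
        b <= a for a, b in zip(edges, edges[1:])
    ):
        raise ValueError("edges must be strictly increasing and positive")
    labels = _bin_labels(edges)
    counts = dict.fromkeys(labels, 0)
    n = 0
    for ap in annotated:
        if ap.nearest_gene is None:
            continue
        n += 1
        d = ap.abs_distance
        for e, lab in zip(edges, labels):
            if d <= e:
                counts[lab] += 1
                break
        else:
            counts[labels[-1]] += 1
    if n == 0:
        return dict.fromkeys(labels, 0.0)
    return {lab: 100.0 * c / n for lab, c in counts.items()}


def _fmt_bp(bp: int) -> str:
    return f"{bp // 1000}kb" if bp % 1000 == 0 else f"{bp}bp"


def _bin_labels(edges: Sequence[int]) -> list[str]:
    labels = [f"0-{_fmt_bp(edges[0])}"]
    labels += [f"{_fmt_bp(a)}-{_fmt_bp(b)}" for a, b in zip(edges, edges[1:])]
    labels.append(f">{_fmt_bp(edges[-1])}")
    return labels


def classify_tss_proximity(
    annotated: Sequence[AnnotatedPeak], proximal_bp: int = 1000
) -> list[str]:
    """Label each peak ``proximal`` or ``distal`` to its nearest TSS.

    Distal means strictly more than ``proximal_bp`` away: a peak at
    exactly 1000 bp is proximal under the default "more than 1 kb"
    rule.  Null-annotated peaks are distal (infinitely far).
    """
    if proximal_bp <= 0:
        raise ValueError("proximal_bp must be positive")
    return [
        "distal" if ap.abs_distance > proximal_bp else "proximal" for ap in annotated
    ]


def read_gene_table(path: str | Path, format: str = "tsv") -> list[GeneRecord]:
    """Read gene records.

    ``tsv``: header columns gene_id, chrom, tss, strand.
    ``bed6``: no header; the TSS is the strand-aware 5' end (start for
    +, end-1 for -).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ("gene_id", "chrom", "tss", "strand") if c not in df.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        return [
            GeneRecord(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
            for r in df.itertuples(index=False)
        ]
    if format == "bed6":
        recs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 6:
                    raise ValueError(f"line {lineno}: BED6 requires 6 fields")
                start, end, strand = int(f[1]), int(f[2]), f[5]
                tss = start if strand == "+" else end - 1
                recs.append(GeneRecord(f[3], f[0], tss, strand))
        return recs
    raise ValueError(f"unknown gene table format {format!r}")


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    rows = sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id))
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in rows],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)
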