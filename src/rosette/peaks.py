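"""Replicate-consensus peak sets and differential-accessibility filtering.

Consensus follows the "minimum of two replicates per condition" rule:
peaks from all replicates of a condition are clustered by >=1 bp
overlap (single linkage) and a cluster is kept when members from at
least ``min_support`` distinct replicates contribute.  The retained
coordinate is the union span of the cluster.

Differential filtering applies FDR and fold-change gates to an
externally produced differential-accessibility table (interval,
log2 fold change, FDR); the count model that produced the table is
out of scope here.  "Decreased" sites at FDR < 0.05 (optionally fold
change < -1.5) are the BRG1-dependent accessible sites of the assay
this package models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval, IntervalSet, cluster_intervals, merge_adjacent

__all__ = [
    "DifferentialPeakRecord",
    "ConsensusPeakSet",
    "consensus_peaks",
    "combine_conditions",
    "filter_differential",
    "read_differential_table",
    "write_differential_table",
]


@dataclass(frozen=True)
class DifferentialPeakRecord:
    """Per-peak differential-accessibility result (treatment over control)."""

    interval: GenomicInterval
    log2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must lie in [0, 1], got {self.fdr}")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"log2fc must be finite, got {self.log2fc}")


@dataclass
class ConsensusPeakSet:
    """Peaks supported by >= min_support replicates of one condition."""

    peaks: IntervalSet
    support: list[int]
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.support) != len(self.peaks):
            raise ValueError("support list must align with peaks")


def consensus_peaks(
    replicates: Sequence[IntervalSet],
    min_support: int = 2,
    condition: str = "",
) -> ConsensusPeakSet:
    """Replicate-consensus peaks for one condition.

    Peaks across replicates are clustered by single-linkage >=1 bp
    overlap; clusters whose members span >= ``min_support`` distinct
    replicates are kept as their union span, with the replicate count
    recorded as support.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if min_support > len(replicates):
        raise ValueError(
            f"min_support={min_support} exceeds the {len(replicates)} replicates supplied"
        )
    tagged: list[GenomicInterval] = []
    origin: dict[tuple[str, int, int, str], set[int]] = {}
    for r, rep in enumerate(replicates):
        for iv in rep:
            # tag provenance via name so clustering stays interval-pure
            key = GenomicInterval(iv.chrom, iv.start, iv.end, name=f"rep{r}:{iv.name or ''}")
            tagged.append(key)
            origin.setdefault((iv.chrom, iv.start, iv.end, key.name), set()).add(r)
    kept: list[GenomicInterval] = []
    support: list[int] = []
    # max_gap=-1: strict overlap, book-ended peaks do not cluster
    for cluster in cluster_intervals(tagged, max_gap=-1):
        reps = set()
        for iv in cluster:
            reps.add(int(iv.name.split(":", 1)[0][3:]))
        if len(reps) >= min_support:
            kept.append(
                GenomicInterval(
                    cluster[0].chrom,
                    min(iv.start for iv in cluster),
                    max(iv.end for iv in cluster),
                )
            )
            support.append(len(reps))
    order = sorted(range(len(kept)), key=lambda i: kept[i].sort_key())
    return ConsensusPeakSet(
        peaks=IntervalSet(kept[i] for i in order),
        support=[support[i] for i in order],
        condition=condition,
    )


def combine_conditions(consensus_sets: Sequence[ConsensusPeakSet]) -> IntervalSet:
    """Union of per-condition consensus sets, merged at gap 0.

    This combined set is the peak universe for downstream counting and
    enrichment.
    """
    if not consensus_sets:
        raise ValueError("at least one consensus set required")
    pooled: list[GenomicInterval] = []
    for cs in consensus_sets:
        pooled.extend(cs.peaks)
    return merge_adjacent(pooled, max_gap=0)


def filter_differential(
    table: Iterable[DifferentialPeakRecord],
    fdr_max: float = 0.05,
    fold_min: float | None = 1.5,
    direction: str = "decreased",
    fold_scale: str = "linear",
) -> IntervalSet:
    """Select differential peaks passing the FDR and fold-change gates.

    Parameters
    ----------
    fdr_max:
        Strict FDR cutoff (records with ``fdr < fdr_max`` pass).
    fold_min:
        Minimum fold change, > 1.  On the default ``linear`` scale the
        decreased gate is linear fold change <= -fold_min, i.e.
        ``log2fc <= -log2(fold_min)`` (fold_min 1.5 ~ |log2fc| >= 0.585);
        with ``fold_scale="log2"`` the threshold is applied to log2fc
        directly.  ``None`` disables the fold gate entirely: only the
        FDR cutoff and the sign of log2fc select records (the FDR-only
        site lists used for overlap analyses).
    direction:
        ``decreased``, ``increased`` or ``both`` (union).
    """
    if direction not in ("decreased", "increased", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if fold_scale not in ("linear", "log2"):
        raise ValueError(f"unknown fold_scale {fold_scale!r}")
    if fold_min is None:
        lfc_min = 0.0
    else:
        if fold_min <= 1.0 and fold_scale == "linear":
            raise ValueError("fold_min must exceed 1 on the linear scale")
        if fold_min <= 0.0:
            raise ValueError("fold_min must be positive")
        lfc_min = math.log2(fold_min) if fold_scale == "linear" else fold_min
    out = []
    for rec in table:
        if rec.fdr >= fdr_max:
            continue
        if fold_min is None:
            dec, inc = rec.log2fc < 0, rec.log2fc > 0
        else:
            dec = rec.log2fc <= -lfc_min
            inc = rec.log2fc >= lfc_min
        if (
            (direction == "decreased" and dec)
            or (direction == "increased" and inc)
            or (direction == "both" and (dec or inc))
        ):
            out.append(rec.interval)
    return IntervalSet(out)


_DIFF_COLUMNS = ["chrom", "start", "end", "log2fc", "fdr"]


def read_differential_table(path: str | Path) -> list[DifferentialPeakRecord]:
    """Read a tab-separated differential table (header: chrom, start,
    end, log2fc, fdr; extra columns tolerated and ignored)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DIFF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"differential table missing columns: {missing}")
    return [
        DifferentialPeakRecord(
            interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
            log2fc=float(row.log2fc),
            fdr=float(row.fdr),
        )
        for row in df.itertuples(index=False)
    ]


def write_differential_table(
    records: Iterable[DifferentialPeakRecord], path: str | Path
) -> None:
    rows = [
        (r.interval.chrom, r.interval.start, r.interval.end, r.log2fc, r.fdr)
        for r in sorted(records, key=lambda r: r.interval.sort_key())
    ]
    pd.DataFrame(rows, columns=_DIFF_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
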