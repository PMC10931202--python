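"""Overlap-enrichment statistics, BH adjustment, multiway set summaries
and binned signal metaprofiles.

The core test is the one-sided (upper-tail) hypergeometric test on the
overlap of two sets drawn from a finite universe: with a universe of
size N, a set A of size K, a set B of size n and an observed overlap
k, p = P(X >= k) for X ~ Hypergeometric(N, K, n), computed exactly in
log space.  Because p-values are acutely sensitive to the universe,
callers supply it explicitly and it is echoed into every result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .intervals import GenomicInterval, IntervalSet, intersect_sets
from .superenhancers import SignalLibrary

__all__ = [
    "OverlapEnrichment",
    "SignalProfile",
    "hypergeometric_enrichment",
    "bh_adjust",
    "multiway_overlap_counts",
    "signal_profile",
    "interval_overlap_enrichment",
]


@dataclass(frozen=True)
class OverlapEnrichment:
    universe_n: int
    set_a_n: int
    set_b_n: int
    overlap_k: int
    p_value: float
    tail: str = "upper"

    def __post_init__(self) -> None:
        if self.overlap_k > min(self.set_a_n, self.set_b_n):
            raise ValueError("overlap exceeds a set size")
        if max(self.set_a_n, self.set_b_n) > self.universe_n:
            raise ValueError("set size exceeds universe")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


def hypergeometric_enrichment(
    universe_n: int,
    set_a_n: int,
    set_b_n: int,
    overlap_k: int,
    tail: str = "upper",
) -> OverlapEnrichment:
    """Exact hypergeometric overlap test.

    Upper tail (default, enrichment): p = P(X >= k).  Lower tail
    (depletion): p = P(X <= k).  Symmetric in the roles of the two
    sets.  Evaluated through the log survival/cumulative function so
    tiny tail probabilities do not underflow prematurely.
    """
    if min(universe_n, set_a_n, set_b_n, overlap_k) < 0:
        raise ValueError("counts must be non-negative")
    if overlap_k > min(set_a_n, set_b_n):
        raise ValueError(
            f"overlap_k={overlap_k} exceeds min(set sizes)={min(set_a_n, set_b_n)}"
        )
    if max(set_a_n, set_b_n) > universe_n:
        raise ValueError("set sizes cannot exceed the universe")
    if overlap_k < set_a_n + set_b_n - universe_n:
        raise ValueError("overlap below the deterministic minimum")
    dist = hypergeom(universe_n, set_a_n, set_b_n)
    if tail == "upper":
        # P(X >= k) = sf(k - 1)
        log_p = dist.logsf(overlap_k - 1)
    elif tail == "lower":
        log_p = dist.logcdf(overlap_k)
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    p = float(np.exp(log_p))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return OverlapEnrichment(universe_n, set_a_n, set_b_n, overlap_k, p, tail=tail)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    adj_i = min_{j >= i} (p_(j) * m / j), capped at 1, returned in the
    original order.  Guarantees adj >= p elementwise and monotonicity
    in the sorted order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj_sorted
    return out


def multiway_overlap_counts(
    named_sets: Mapping[str, set | frozenset | IntervalSet],
    min_bp: int = 1,
) -> list[dict]:
    """UpSet-style exclusive-combination counts for 2–4 named sets.

    Gene-id (hashable) sets are partitioned exactly: each element falls
    in the cell of the sets containing it.  Interval sets use the
    >=1 bp overlap rule: each interval of each source set is assigned
    to the combination of all sets it overlaps, and counts are
    reported per source set (an interval "cell count" is asymmetric
    under overlap, unlike exact membership).

    Returns one row per non-empty combination:
    ``{"combination": tuple(names), "counts": {source: n, ...}, "total": n}``
    sorted by combination size then name.
    """
    names = list(named_sets)
    if not (2 <= len(names) <= 4):
        raise ValueError("between 2 and 4 named sets required")
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    first = next(iter(named_sets.values()))
    cells: dict[tuple[str, ...], dict[str, int]] = {}

    if isinstance(first, IntervalSet):
        overlap_map: dict[tuple[str, str], set[int]] = {}
        for src in names:
            src_set: IntervalSet = named_sets[src]  # type: ignore[assignment]
            index = {
                (iv.chrom, iv.start, iv.end, iv.name or ""): i
                for i, iv in enumerate(src_set)
            }
            for other in names:
                if other == src:
                    continue
                hit: set[int] = set()
                res = intersect_sets(src_set, named_sets[other], min_bp=min_bp)  # type: ignore[arg-type]
                for a, _ in res.pairs:
                    hit.add(index[(a.chrom, a.start, a.end, a.name or "")])
                overlap_map[(src, other)] = hit
            for i in range(len(src_set)):
                combo = tuple(
                    nm
                    for nm in names
                    if nm == src or i in overlap_map[(src, nm)]
                )
                cells.setdefault(combo, {})[src] = (
                    cells.setdefault(combo, {}).get(src, 0) + 1
                )
    else:
        universe = set()
        for s in named_sets.values():
            universe |= set(s)  # type: ignore[arg-type]
        for el in universe:
            combo = tuple(nm for nm in names if el in named_sets[nm])  # type: ignore[operator]
            cell = cells.setdefault(combo, {})
            for nm in combo:
                cell[nm] = cell.get(nm, 0) + 1

    rows = []
    for combo in sorted(cells, key=lambda c: (len(c), c)):
        counts = cells[combo]
        total = (
            counts[combo[0]]
            if not isinstance(first, IntervalSet)
            else sum(counts.values())
        )
        rows.append({"combination": combo, "counts": dict(counts), "total": total})
    return rows


@dataclass
class SignalProfile:
    """Average binned signal around site centers (a metaprofile)."""

    bin_edges: np.ndarray  # offsets relative to center, len = n_bins + 1
    mean_signal: np.ndarray  # mean CPM per bin across sites
    n_sites: int
    class_label: str = ""

    @property
    def offsets(self) -> np.ndarray:
        """Bin midpoints relative to the site center."""
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def signal_profile(
    sites: IntervalSet,
    signal: SignalLibrary,
    half_window_bp: int = 2000,
    bin_bp: int = 100,
    class_label: str = "",
) -> SignalProfile:
    """Binned fragment-midpoint metaprofile around site centers.

    For each site, fragments are counted per ``bin_bp`` bin across
    ``[center - half_window, center + half_window)``, converted to
    CPM against the library size, and averaged across sites.  The
    defaults give 40 bins of 100 bp spanning +/-2 kb.
    """
    if len(sites) == 0:
        raise ValueError("at least one site required")
    if half_window_bp % bin_bp != 0:
        raise ValueError("half_window_bp must be divisible by bin_bp")
    n_bins = 2 * half_window_bp // bin_bp
    edges = np.arange(-half_window_bp, half_window_bp + bin_bp, bin_bp)
    total = np.zeros(n_bins, dtype=float)
    for site in sites:
        center = site.center
        counts = np.array(
            [
                signal.count_in(
                    GenomicInterval(
                        site.chrom,
                        max(0, center + int(edges[b])),
                        max(1, center + int(edges[b + 1])),
                    )
                )
                if center + int(edges[b + 1]) > 0
                else 0
                for b in range(n_bins)
            ],
            dtype=float,
        )
        total += counts
    mean_cpm = total / signal.library_size * 1e6 / len(sites)
    return SignalProfile(
        bin_edges=edges, mean_signal=mean_cpm, n_sites=len(sites), class_label=class_label
    )


def interval_overlap_enrichment(
    universe: IntervalSet,
    set_a: IntervalSet,
    set_b: IntervalSet,
    min_bp: int = 1,
) -> OverlapEnrichment:
    """Hypergeometric enrichment of two interval sets over a peak universe.

    Universe members are classified by >=1 bp overlap with each set;
    the test is then the exact hypergeometric on those membership
    counts.  The universe is typically the combined consensus peak
    set.
    """
    in_a = {
        (u.chrom, u.start, u.end)
        for u, _ in intersect_sets(universe, set_a, min_bp=min_bp).pairs
    }
    in_b = {
        (u.chrom, u.start, u.end)
        for u, _ in intersect_sets(universe, set_b, min_bp=min_bp).pairs
    }
    return hypergeometric_enrichment(
        len(universe), len(in_a), len(in_b), len(in_a & in_b)
    )
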