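"""Independent brute-force oracles used by the test suite.

Each oracle deliberately takes the naive route — all-pairs scans,
per-base bitmaps, union-find connectivity, exact rational arithmetic,
geometric line scans — so that agreement with the package's sweep- and
log-space implementations is informative.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np

from rosette.intervals import GenomicInterval


def allpairs_overlap_pairs(a, b, min_bp=1):
    """All (i, j) index pairs whose intervals share >= min_bp bases."""
    out = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom == y.chrom and min(x.end, y.end) - max(x.start, y.start) >= min_bp:
                out.append((i, j))
    return out


def bitmap_union_bases(intervals, chrom_lengths):
    """Per-base union size via an explicit coverage bitmap."""
    total = 0
    for chrom, length in chrom_lengths.items():
        cov = np.zeros(length, dtype=bool)
        for iv in intervals:
            if iv.chrom == chrom:
                cov[iv.start : iv.end] = True
        total += int(cov.sum())
    return total


def bitmap_merged_intervals(intervals, chrom_lengths):
    """Maximal covered runs from a coverage bitmap (gap-0 merge oracle)."""
    out = []
    for chrom in sorted(chrom_lengths):
        cov = np.zeros(chrom_lengths[chrom] + 1, dtype=np.int8)
        present = False
        for iv in intervals:
            if iv.chrom == chrom:
                cov[iv.start : iv.end] = 1
                present = True
        if not present:
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], cov))))
        starts, ends = edges[::2], edges[1::2]
        for s, e in zip(starts, ends):
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def unionfind_merge(intervals, max_gap):
    """Transitive-closure merge via explicit union-find over all pairs."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom:
                continue
            gap = max(b.start - a.end, a.start - b.end)
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    spans = [
        GenomicInterval(
            g[0].chrom, min(iv.start for iv in g), max(iv.end for iv in g)
        )
        for g in groups.values()
    ]
    return sorted(spans, key=lambda iv: iv.sort_key())


def nearest_tss_scan(peak, genes):
    """Exhaustive nearest-TSS assignment for one peak."""
    center = (peak.start + peak.end) // 2
    same = [g for g in genes if g.chrom == peak.chrom]
    if not same:
        return None, float("inf")
    best = min(abs(center - g.tss) for g in same)
    gene = min((g for g in same if abs(center - g.tss) == best), key=lambda g: g.gene_id)
    signed = center - gene.tss
    if gene.strand == "-":
        signed = -signed
    return gene.gene_id, signed


def hypergeom_upper_tail_exact(N, K, n, k):
    """P(X >= k) by exact rational summation of the hypergeometric pmf."""
    denom = comb(N, n)
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return total


def hypergeom_by_enumeration(N, K, n, k):
    """P(X >= k) by literally enumerating every size-n draw (tiny N only)."""
    hits = 0
    total = 0
    marked = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def bh_stepup(p):
    """Independent BH step-up: literal textbook loop, no vectorization."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


def tangent_cutoff_scan(scores):
    """Slope-1 tangent by testing every index as the touch point.

    For each candidate index, draw the slope-1 line through its scaled
    (rank, signal) point and keep candidates with no point strictly
    below the line; the cutoff is the highest-rank candidate.  Returns
    (cutoff_index_0based, cutoff_score) or (None, None) when no call
    is possible.
    """
    s = sorted(scores)
    n = len(s)
    if n < 2:
        return None, None
    shift = min(min(s), 0.0)
    shifted = [v - shift for v in s]
    top = max(shifted)
    if top <= 0:
        return None, None
    y = [v / top for v in shifted]
    x = [(i + 1) / n for i in range(n)]
    candidates = []
    tol = 1e-9  # same near-tie rule as the caller: part of the contract
    for i in range(n):
        intercept = y[i] - x[i]
        if all(y[j] - x[j] >= intercept - tol for j in range(n)):
            candidates.append(i)
    cut = max(candidates)
    return cut, s[cut]


def super_scores_by_scan(scores):
    """Multiset of scores the tangent-scan oracle calls super."""
    cut, cutoff_score = tangent_cutoff_scan(scores)
    if cut is None:
        return []
    s = sorted(scores)
    return [v for i, v in enumerate(s) if i > cut and v > cutoff_score]


def random_intervals(rng, n, chroms=("chrA", "chrB"), length=100_000, max_width=2_000):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, length - max_width))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width))
    return out
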