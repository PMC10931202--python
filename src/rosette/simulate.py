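"""Seeded synthetic genome with planted regulatory ground truth.

The generator lays out a toy multi-chromosome genome on a grid of
non-overlapping placement blocks, one planted element group per
block: a gene with its promoter marks, a TSS-distal typical enhancer,
or a cluster of enhancer constituents with intra-cluster gaps drawn
below the 12.5 kb stitch distance (a plantable super-enhancer).  The
block margins guarantee that distinct groups sit far enough apart
(>= 40 kb) that stitching can never bridge them and no enhancer falls
within 1 kb of a TSS — the structural invariants the downstream
pipeline is tested against.

Emitted tracks:

* histone-mark peak sets — H3K4me3 + H3K27ac at promoters,
  H3K27ac + H3K4me1 at enhancers (noise-free intervals);
* an H3K27ac fragment library with the super-enhancer constituents
  carrying a configurable signal multiplier, plus a uniform
  control/input fragment library;
* per-replicate ATAC peak sets per condition, with optional dropout,
  edge jitter and replicate-private noise peaks;
* a differential-accessibility table derived from simulated
  negative-binomial replicate counts.  A configurable subset of
  distal sites ("BRG1-dependent": a chosen fraction of typical
  enhancers and of super-enhancer clusters) has its treatment mean
  scaled by ``2**planted_log2fc``.

The differential statistics are a synthetic stand-in: a Wald test on
the log2 fold change of negative-binomial replicate means, using the
generating dispersion shared across sites, with Benjamini–Hochberg
adjustment — standing in structurally for the count-model output the
pipeline normally ingests.  With ``noise=False`` the table carries
the exact planted effects (FDR 0 at planted sites, 1 elsewhere) and
all stochastic placement becomes deterministic.

Everything is driven by one :func:`numpy.random.default_rng` stream,
so a given (config, seed) pair reproduces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .annotation import GeneRecord, read_gene_table, write_gene_table
from .enrichment import bh_adjust
from .intervals import GenomicInterval, IntervalSet, read_peaks, write_bed
from .peaks import (
    DifferentialPeakRecord,
    read_differential_table,
    write_differential_table,
)
from .superenhancers import SignalLibrary

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticBundle", "generate", "write_bundle", "read_bundle"]

_BLOCK_BP = 100_000
_BLOCK_MARGIN = 20_000
_ENH_WIDTH = 800
_PROM_MARK_HALF = 600
_ATAC_HALF = 300
_FRAG_LEN = 200


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic bundle.

    Defaults emulate the scale of the modelled assay in miniature: a
    15 Mb genome, three ATAC replicates per condition, overdispersed
    replicate counts, a 10x H3K27ac excess at super-enhancer
    constituents, and 75% of distal sites / super-enhancer clusters
    planted as BRG1-dependent with a -2 log2 fold change.
    """

    seed: int = 0
    n_chroms: int = 5
    chrom_len_bp: int = 3_000_000
    n_genes: int = 60
    n_typical_enhancers: int = 40
    n_se_clusters: int = 8
    se_cluster_size: tuple[int, int] = (3, 5)
    se_signal_multiplier: float = 10.0
    frac_brg1_dependent_distal: float = 0.75
    frac_brg1_dependent_se: float = 0.75
    planted_log2fc: float = -2.0
    replicates: int = 3
    nb_dispersion: float = 0.05
    background_peak_rate: float = 2e-6  # ATAC background peaks per bp
    bg_fragment_rate: float = 2e-3  # background fragments per bp per library
    enhancer_fragment_mean: float = 60.0  # H3K27ac fragments per typical enhancer
    atac_mean_count: float = 150.0  # baseline ATAC replicate count per site
    detect_prob: float = 0.95  # per-replicate peak detection probability
    noise: bool = True

    def __post_init__(self) -> None:
        for name in ("frac_brg1_dependent_distal", "frac_brg1_dependent_se"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.se_cluster_size
        if not (1 <= lo <= hi):
            raise ValueError("se_cluster_size must be a (lo, hi) range with 1 <= lo <= hi")
        if self.replicates < 2:
            raise ValueError("at least two replicates required")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")


@dataclass
class GroundTruth:
    """Planted element locations and effects, for recovery scoring."""

    planted_promoters: IntervalSet
    planted_enhancers: IntervalSet  # typical enhancers + SE constituents
    planted_se_regions: IntervalSet  # expected stitched spans
    brg1_dependent_sites: IntervalSet
    brg1_dependent_se_regions: IntervalSet
    true_log2fc: dict[tuple[str, int, int], float]


@dataclass
class SyntheticBundle:
    """Everything the pipeline ingests, plus the ground truth."""

    config: SyntheticConfig
    genome: dict[str, int]
    genes: list[GeneRecord]
    atac_replicates: dict[str, list[IntervalSet]]  # condition -> per-replicate sets
    h3k4me3: IntervalSet
    h3k4me1: IntervalSet
    h3k27ac: IntervalSet
    h3k27ac_library: SignalLibrary
    input_library: SignalLibrary
    differential: list[DifferentialPeakRecord]
    truth: GroundTruth

    CONDITIONS = ("control", "treatment")


def _place_blocks(cfg: SyntheticConfig, rng: np.random.Generator):
    """Assign one role per placement block; order is rng-shuffled."""
    blocks = [
        (f"chr{c + 1}", b * _BLOCK_BP)
        for c in range(cfg.n_chroms)
        for b in range(cfg.chrom_len_bp // _BLOCK_BP)
    ]
    n_needed = cfg.n_genes + cfg.n_typical_enhancers + cfg.n_se_clusters
    if n_needed > len(blocks):
        raise ValueError(
            f"genome too small: {n_needed} element groups requested but only "
            f"{len(blocks)} placement blocks available"
        )
    order = rng.permutation(len(blocks))
    roles = (
        ["gene"] * cfg.n_genes
        + ["typical"] * cfg.n_typical_enhancers
        + ["se"] * cfg.n_se_clusters
    )
    return [(blocks[order[i]], roles[i]) for i in range(n_needed)]


def _jitter(rng: np.random.Generator, span: int, noise: bool) -> int:
    return int(rng.integers(0, span)) if noise else span // 2


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full synthetic input bundle with planted truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genome = {f"chr{c + 1}": cfg.chrom_len_bp for c in range(cfg.n_chroms)}
    usable = _BLOCK_BP - 2 * _BLOCK_MARGIN

    genes: list[GeneRecord] = []
    h3k4me3: list[GenomicInterval] = []
    h3k4me1: list[GenomicInterval] = []
    h3k27ac: list[GenomicInterval] = []
    promoters: list[GenomicInterval] = []
    typical: list[GenomicInterval] = []
    se_constituents: list[list[GenomicInterval]] = []
    se_regions: list[GenomicInterval] = []
    # master ATAC site list: (interval, kind, group_index)
    atac_sites: list[tuple[GenomicInterval, str, int]] = []

    gi = ti = si = 0
    for (chrom, block_start), role in _place_blocks(cfg, rng):
        lo = block_start + _BLOCK_MARGIN
        if role == "gene":
            tss = lo + _jitter(rng, usable, cfg.noise)
            strand = "+" if (not cfg.noise or rng.random() < 0.5) else "-"
            genes.append(GeneRecord(f"gene{gi:04d}", chrom, tss, strand))
            prom27 = GenomicInterval(chrom, tss - 500, tss + 500)
            h3k4me3.append(GenomicInterval(chrom, tss - _PROM_MARK_HALF, tss + _PROM_MARK_HALF))
            h3k27ac.append(prom27)
            promoters.append(prom27)
            atac_sites.append(
                (GenomicInterval(chrom, tss - _ATAC_HALF, tss + _ATAC_HALF), "promoter", gi)
            )
            gi += 1
        elif role == "typical":
            c = lo + _jitter(rng, usable, cfg.noise)
            enh = GenomicInterval(chrom, c - _ENH_WIDTH // 2, c + _ENH_WIDTH // 2)
            typical.append(enh)
            h3k27ac.append(enh)
            h3k4me1.append(GenomicInterval(chrom, enh.start - 100, enh.end + 100))
            atac_sites.append(
                (GenomicInterval(chrom, c - _ATAC_HALF, c + _ATAC_HALF), "typical", ti)
            )
            ti += 1
        else:  # SE cluster
            lo_n, hi_n = cfg.se_cluster_size
            k = int(rng.integers(lo_n, hi_n + 1)) if cfg.noise else (lo_n + hi_n) // 2
            gaps = (
                rng.integers(1_000, 12_001, size=max(k - 1, 0))
                if cfg.noise
                else np.full(max(k - 1, 0), 6_000)
            )
            span = k * _ENH_WIDTH + int(np.sum(gaps))
            slack = usable - span
            if slack < 0:
                raise ValueError(
                    "se_cluster_size too large for the placement block; "
                    "reduce cluster size or gap range"
                )
            start = lo + _jitter(rng, slack + 1, cfg.noise)
            members = []
            pos = start
            for j in range(k):
                enh = GenomicInterval(chrom, pos, pos + _ENH_WIDTH)
                members.append(enh)
                h3k27ac.append(enh)
                h3k4me1.append(GenomicInterval(chrom, enh.start - 100, enh.end + 100))
                atac_sites.append(
                    (
                        GenomicInterval(chrom, enh.center - _ATAC_HALF, enh.center + _ATAC_HALF),
                        "se",
                        si,
                    )
                )
                if j < k - 1:
                    pos = enh.end + int(gaps[j])
            se_constituents.append(members)
            se_regions.append(
                GenomicInterval(chrom, members[0].start, members[-1].end, name=f"se{si:03d}")
            )
            si += 1

    # background ATAC peaks (not differential, support in both conditions)
    total_len = cfg.n_chroms * cfg.chrom_len_bp
    n_bg = (
        int(rng.poisson(cfg.background_peak_rate * total_len))
        if cfg.noise
        else int(round(cfg.background_peak_rate * total_len))
    )
    chrom_names = list(genome)
    for b in range(n_bg):
        chrom = chrom_names[int(rng.integers(0, cfg.n_chroms))]
        # keep clear of chromosome ends so replicate edge jitter stays in-bounds
        pos = int(rng.integers(400, cfg.chrom_len_bp - 400))
        atac_sites.append(
            (GenomicInterval(chrom, pos - 200, pos + 200), "background", b)
        )

    # ---- planted BRG1 dependence -------------------------------------
    n_dep_typ = int(round(cfg.frac_brg1_dependent_distal * cfg.n_typical_enhancers))
    dep_typ = set(
        rng.choice(cfg.n_typical_enhancers, size=n_dep_typ, replace=False).tolist()
        if cfg.n_typical_enhancers
        else []
    )
    n_dep_se = int(round(cfg.frac_brg1_dependent_se * cfg.n_se_clusters))
    dep_se = set(
        rng.choice(cfg.n_se_clusters, size=n_dep_se, replace=False).tolist()
        if cfg.n_se_clusters
        else []
    )

    site_lfc = np.zeros(len(atac_sites))
    for idx, (_, kind, group) in enumerate(atac_sites):
        if (kind == "typical" and group in dep_typ) or (kind == "se" and group in dep_se):
            site_lfc[idx] = cfg.planted_log2fc

    # ---- replicate ATAC peak sets ------------------------------------
    atac_replicates: dict[str, list[IntervalSet]] = {}
    for cond in SyntheticBundle.CONDITIONS:
        reps = []
        for _ in range(cfg.replicates):
            ivs = []
            for iv, _, _ in atac_sites:
                if cfg.noise:
                    if rng.random() >= cfg.detect_prob:
                        continue
                    ds, de = int(rng.integers(-50, 51)), int(rng.integers(-50, 51))
                    ivs.append(GenomicInterval(iv.chrom, iv.start + ds, iv.end + de))
                else:
                    ivs.append(iv)
            if cfg.noise:
                # replicate-private noise peaks: dropped by the 2-replicate rule
                for _ in range(int(rng.poisson(10))):
                    chrom = chrom_names[int(rng.integers(0, cfg.n_chroms))]
                    pos = int(rng.integers(200, cfg.chrom_len_bp - 200))
                    ivs.append(GenomicInterval(chrom, pos - 150, pos + 150))
            reps.append(IntervalSet(ivs, genome=genome))
        atac_replicates[cond] = reps

    # ---- H3K27ac and input fragment libraries ------------------------
    frag_t: list[GenomicInterval] = []
    for enh in promoters:
        frag_t.extend(_element_fragments(rng, enh, cfg.enhancer_fragment_mean, cfg.noise, genome))
    for enh in typical:
        frag_t.extend(_element_fragments(rng, enh, cfg.enhancer_fragment_mean, cfg.noise, genome))
    for members in se_constituents:
        for enh in members:
            frag_t.extend(
                _element_fragments(
                    rng, enh, cfg.enhancer_fragment_mean * cfg.se_signal_multiplier,
                    cfg.noise, genome,
                )
            )
    frag_t.extend(_background_fragments(rng, genome, cfg.bg_fragment_rate, cfg.noise))
    frag_c = _background_fragments(rng, genome, cfg.bg_fragment_rate, cfg.noise)

    h3k27ac_lib = SignalLibrary(IntervalSet(frag_t, genome=genome))
    input_lib = SignalLibrary(IntervalSet(frag_c, genome=genome))

    # ---- differential table ------------------------------------------
    differential = _differential_table(rng, cfg, atac_sites, site_lfc)

    dep_sites = IntervalSet(
        iv for (iv, _, _), lfc in zip(atac_sites, site_lfc) if lfc != 0.0
    )
    truth = GroundTruth(
        planted_promoters=IntervalSet(promoters),
        planted_enhancers=IntervalSet(
            typical + [e for mem in se_constituents for e in mem]
        ),
        planted_se_regions=IntervalSet(se_regions),
        brg1_dependent_sites=dep_sites,
        brg1_dependent_se_regions=IntervalSet(
            r for i, r in enumerate(se_regions) if i in dep_se
        ),
        true_log2fc={
            (iv.chrom, iv.start, iv.end): float(lfc)
            for (iv, _, _), lfc in zip(atac_sites, site_lfc)
        },
    )
    return SyntheticBundle(
        config=cfg,
        genome=genome,
        genes=genes,
        atac_replicates=atac_replicates,
        h3k4me3=IntervalSet(h3k4me3, genome=genome),
        h3k4me1=IntervalSet(h3k4me1, genome=genome),
        h3k27ac=IntervalSet(h3k27ac, genome=genome),
        h3k27ac_library=h3k27ac_lib,
        input_library=input_lib,
        differential=differential,
        truth=truth,
    )


def _element_fragments(rng, element, mean, noise, genome) -> list[GenomicInterval]:
    """Fixed-length fragments whose midpoints fall inside the element."""
    n = int(rng.poisson(mean)) if noise else int(round(mean))
    if n == 0:
        return []
    if noise:
        mids = rng.integers(element.start, element.end, size=n)
    else:
        mids = np.linspace(element.start, element.end - 1, n).astype(int)
    limit = genome[element.chrom]
    out = []
    for m in mids:
        s = max(0, int(m) - _FRAG_LEN // 2)
        out.append(GenomicInterval(element.chrom, s, min(limit, s + _FRAG_LEN)))
    return out


def _background_fragments(rng, genome, rate, noise) -> list[GenomicInterval]:
    out = []
    for chrom, length in genome.items():
        n = int(rng.poisson(rate * length)) if noise else int(round(rate * length))
        if noise:
            mids = rng.integers(_FRAG_LEN, length - _FRAG_LEN, size=n)
        else:
            mids = np.linspace(_FRAG_LEN, length - _FRAG_LEN, n).astype(int)
        for m in mids:
            s = int(m) - _FRAG_LEN // 2
            out.append(GenomicInterval(chrom, s, s + _FRAG_LEN))
    return out


def _differential_table(rng, cfg, atac_sites, site_lfc) -> list[DifferentialPeakRecord]:
    """Synthetic differential-accessibility table.

    Stand-in for an upstream negative-binomial count-model fit: NB
    replicate counts are drawn per condition and compared with a Wald
    test on the log2 fold change whose standard error uses the
    generating dispersion — mirroring the information sharing a real
    dispersion-moderated model achieves — followed by BH adjustment.
    With noise off the table simply carries the planted effects
    exactly.
    """
    records = []
    if not cfg.noise or cfg.nb_dispersion == 0:
        for (iv, _, _), lfc in zip(atac_sites, site_lfc):
            records.append(
                DifferentialPeakRecord(iv, float(lfc), 0.0 if lfc != 0.0 else 1.0)
            )
        return records
    n_sites = len(atac_sites)
    mu = np.full(n_sites, cfg.atac_mean_count)
    mu_t = mu * np.power(2.0, site_lfc)
    size = 1.0 / cfg.nb_dispersion  # NB shape: var = mu + dispersion * mu^2
    counts_c = rng.negative_binomial(
        size, size / (size + mu[:, None]), size=(n_sites, cfg.replicates)
    )
    counts_t = rng.negative_binomial(
        size, size / (size + mu_t[:, None]), size=(n_sites, cfg.replicates)
    )
    mean_c = counts_c.mean(axis=1) + 0.5
    mean_t = counts_t.mean(axis=1) + 0.5
    lfc_hat = np.log2(mean_t / mean_c)
    # delta-method variance of log2(mean) under NB sampling at the
    # estimated mean, dispersion shared across sites
    ln2_sq = np.log(2.0) ** 2
    var_c = (1.0 / mean_c + cfg.nb_dispersion) / (cfg.replicates * ln2_sq)
    var_t = (1.0 / mean_t + cfg.nb_dispersion) / (cfg.replicates * ln2_sq)
    z = lfc_hat / np.sqrt(var_c + var_t)
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = bh_adjust(p)
    for (iv, _, _), l, f in zip(atac_sites, lfc_hat, fdr):
        records.append(DifferentialPeakRecord(iv, float(l), float(f)))
    return records


# ---------------------------------------------------------------------------
# on-disk bundle


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> list[Path]:
    """Write the bundle in the formats the pipeline reads.

    Deterministic: the same (config, seed) pair produces byte-identical
    files.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _write(name, writer):
        p = outdir / name
        writer(p)
        paths.append(p)

    _write(
        "genome.tsv",
        lambda p: pd.DataFrame(
            sorted(bundle.genome.items()), columns=["chrom", "length"]
        ).to_csv(p, sep="\t", index=False),
    )
    _write("genes.tsv", lambda p: write_gene_table(bundle.genes, p))
    for cond, reps in sorted(bundle.atac_replicates.items()):
        for i, rep in enumerate(reps, start=1):
            _write(f"atac_{cond}_rep{i}.bed", lambda p, r=rep: write_bed(r, p))
    for mark in ("h3k4me3", "h3k4me1", "h3k27ac"):
        _write(f"{mark}.bed", lambda p, m=mark: write_bed(getattr(bundle, m), p))
    _write(
        "h3k27ac_fragments.bed",
        lambda p: write_bed(bundle.h3k27ac_library.fragments, p),
    )
    _write(
        "input_fragments.bed", lambda p: write_bed(bundle.input_library.fragments, p)
    )
    _write(
        "differential.tsv", lambda p: write_differential_table(bundle.differential, p)
    )
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, iset in (
        ("promoters", bundle.truth.planted_promoters),
        ("enhancers", bundle.truth.planted_enhancers),
        ("se_regions", bundle.truth.planted_se_regions),
        ("brg1_dependent_sites", bundle.truth.brg1_dependent_sites),
        ("brg1_dependent_se_regions", bundle.truth.brg1_dependent_se_regions),
    ):
        p = truth_dir / f"{name}.bed"
        write_bed(iset, p)
        paths.append(p)
    cfg_dict = dataclasses.asdict(bundle.config)
    cfg_dict["se_cluster_size"] = list(cfg_dict["se_cluster_size"])
    _write(
        "config.yaml",
        lambda p: p.write_text(yaml.safe_dump(cfg_dict, sort_keys=True)),
    )
    return paths


def read_bundle(outdir: str | Path) -> SyntheticBundle:
    """Read a written bundle back (ground truth included)."""
    outdir = Path(outdir)
    cfg_dict = yaml.safe_load((outdir / "config.yaml").read_text())
    cfg_dict["se_cluster_size"] = tuple(cfg_dict["se_cluster_size"])
    cfg = SyntheticConfig(**cfg_dict)
    genome_df = pd.read_csv(outdir / "genome.tsv", sep="\t")
    genome = dict(zip(genome_df.chrom.astype(str), genome_df.length.astype(int)))
    genes = read_gene_table(outdir / "genes.tsv")
    atac: dict[str, list[IntervalSet]] = {}
    for cond in SyntheticBundle.CONDITIONS:
        reps = []
        for i in range(1, cfg.replicates + 1):
            reps.append(read_peaks(outdir / f"atac_{cond}_rep{i}.bed", genome=genome))
        atac[cond] = reps
    truth_dir = outdir / "truth"
    dep_sites = read_peaks(truth_dir / "brg1_dependent_sites.bed")
    truth = GroundTruth(
        planted_promoters=read_peaks(truth_dir / "promoters.bed"),
        planted_enhancers=read_peaks(truth_dir / "enhancers.bed"),
        planted_se_regions=read_peaks(truth_dir / "se_regions.bed"),
        brg1_dependent_sites=dep_sites,
        brg1_dependent_se_regions=read_peaks(truth_dir / "brg1_dependent_se_regions.bed"),
        true_log2fc={},
    )
    return SyntheticBundle(
        config=cfg,
        genome=genome,
        genes=genes,
        atac_replicates=atac,
        h3k4me3=read_peaks(outdir / "h3k4me3.bed", genome=genome),
        h3k4me1=read_peaks(outdir / "h3k4me1.bed", genome=genome),
        h3k27ac=read_peaks(outdir / "h3k27ac.bed", genome=genome),
        h3k27ac_library=SignalLibrary(read_peaks(outdir / "h3k27ac_fragments.bed")),
        input_library=SignalLibrary(read_peaks(outdir / "input_fragments.bed")),
        differential=read_differential_table(outdir / "differential.tsv"),
        truth=truth,
    )
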