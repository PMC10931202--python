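"""End-to-end orchestration: consensus → differential filter → annotate
→ classify → stitch/call super-enhancers → enrichment → report.

The pipeline is a pure function of its inputs and configuration:
re-running on the same bundle with the same config reproduces
byte-identical output files (verified via the sha256 manifest it
writes).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import (
    DEFAULT_DISTANCE_EDGES,
    annotate_nearest_tss,
    bin_tss_distances,
    classify_tss_proximity,
)
from .elements import active_enhancers, classify_elements
from .enrichment import interval_overlap_enrichment
from .intervals import IntervalSet, intersect_sets, write_bed
from .peaks import combine_conditions, consensus_peaks, filter_differential
from .simulate import SyntheticBundle
from .superenhancers import (
    DEFAULT_STITCH_BP,
    call_superenhancers,
    hockey_stick_report,
    score_regions,
    stitch_enhancers,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_outputs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds in one place; defaults are the
    conventional values of the modelled analysis (FDR 0.05, linear
    fold change 1.5, 1 kb promoter proximity, 12.5 kb stitching,
    2-replicate consensus)."""

    fdr_max: float = 0.05
    fold_min: float = 1.5
    proximal_bp: int = 1000
    stitch_bp: int = DEFAULT_STITCH_BP
    min_support: int = 2
    distance_edges: tuple[int, ...] = DEFAULT_DISTANCE_EDGES
    # the overlap analyses (enhancer/SE vs decreased sites) use the
    # FDR-only decreased list; the fold gate applies to the headline
    # "dependent accessible sites" list
    overlap_fdr_only: bool = True

    def __post_init__(self) -> None:
        if min(self.fdr_max, self.fold_min, self.proximal_bp, self.stitch_bp) <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass
class PipelineResult:
    config: RunConfig
    universe: IntervalSet
    decreased_sites: IntervalSet  # FDR + fold gate
    decreased_fdr_only: IntervalSet
    distance_bins: dict[str, float]
    elements: list
    enhancers: IntervalSet
    stitched: list
    cutoff_score: float | None
    hockey: dict
    enhancer_enrichment: object
    se_decreased_fraction: float
    summary: dict = field(default_factory=dict)


def _check_namespace(bundle: SyntheticBundle) -> None:
    known = set(bundle.genome)
    offenders = set()
    tracks = [bundle.h3k4me3, bundle.h3k4me1, bundle.h3k27ac]
    tracks += [r for reps in bundle.atac_replicates.values() for r in reps]
    for track in tracks:
        offenders |= set(track.chroms()) - known
    offenders |= {g.chrom for g in bundle.genes} - known
    if offenders:
        raise ValueError(
            f"chromosome namespace mismatch: {sorted(offenders)} absent from genome table"
        )


def run_pipeline(bundle: SyntheticBundle, config: RunConfig = RunConfig()) -> PipelineResult:
    """Run every stage on an input bundle and assemble the summary."""
    _check_namespace(bundle)
    cfg = config

    consensus = [
        consensus_peaks(reps, min_support=cfg.min_support, condition=cond)
        for cond, reps in sorted(bundle.atac_replicates.items())
    ]
    universe = combine_conditions(consensus)
    logger.info("consensus universe: %d peaks", len(universe))

    decreased = filter_differential(
        bundle.differential, cfg.fdr_max, cfg.fold_min, "decreased"
    )
    decreased_fdr_only = filter_differential(
        bundle.differential, cfg.fdr_max, None, "decreased"
    )
    overlap_set = decreased_fdr_only if cfg.overlap_fdr_only else decreased

    annotated = annotate_nearest_tss(universe, bundle.genes)
    distance_bins = bin_tss_distances(annotated, cfg.distance_edges)
    proximity = classify_tss_proximity(annotated, cfg.proximal_bp)

    elements = classify_elements(
        None,
        bundle.h3k4me3,
        bundle.h3k4me1,
        bundle.h3k27ac,
        bundle.genes,
        proximal_bp=cfg.proximal_bp,
    )
    enhancers = active_enhancers(elements)

    stitched = stitch_enhancers(enhancers, cfg.stitch_bp)
    score_regions(stitched, bundle.h3k27ac_library, bundle.input_library)
    stitched, cutoff = call_superenhancers(stitched)
    hockey = hockey_stick_report(stitched, cutoff)

    supers = IntervalSet(r.interval for r in stitched if r.is_super)
    if len(supers) and len(overlap_set):
        se_hit = intersect_sets(supers, overlap_set).a_overlapping
        se_frac = se_hit / len(supers)
    else:
        se_frac = 0.0

    enh_enr = (
        interval_overlap_enrichment(universe, enhancers, overlap_set)
        if len(universe)
        else None
    )

    summary = {
        "n_consensus_peaks": len(universe),
        "n_decreased_sites": len(decreased),
        "n_decreased_fdr_only": len(decreased_fdr_only),
        "n_promoters": sum(1 for e in elements if e.element_class == "promoter"),
        "n_enhancers": len(enhancers),
        "n_unclassified": sum(1 for e in elements if e.element_class == "unclassified"),
        "n_stitched_regions": len(stitched),
        "n_superenhancers": hockey["n_super"],
        "n_typical_regions": hockey["n_typical"],
        "se_cutoff_score": cutoff,
        "se_decreased_fraction": se_frac,
        "pct_universe_distal": 100.0 * proximity.count("distal") / len(proximity)
        if proximity
        else 0.0,
        "distance_bins_pct": distance_bins,
        "enhancer_decreased_overlap_p": enh_enr.p_value if enh_enr else None,
    }
    return PipelineResult(
        config=cfg,
        universe=universe,
        decreased_sites=decreased,
        decreased_fdr_only=decreased_fdr_only,
        distance_bins=distance_bins,
        elements=elements,
        enhancers=enhancers,
        stitched=stitched,
        cutoff_score=cutoff,
        hockey=hockey,
        enhancer_enrichment=enh_enr,
        se_decreased_fraction=se_frac,
        summary=summary,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(result: PipelineResult, outdir: str | Path) -> dict[str, str]:
    """Write stage outputs plus a sha256 manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(result.universe, outdir / "consensus_universe.bed")
    write_bed(result.decreased_sites, outdir / "decreased_sites.bed")
    write_bed(result.decreased_fdr_only, outdir / "decreased_sites_fdr_only.bed")
    for cls in ("promoter", "enhancer", "unclassified"):
        write_bed(
            (e.interval for e in result.elements if e.element_class == cls),
            outdir / f"elements_{cls}.bed",
        )
    pd.DataFrame(result.hockey["table"]).to_csv(
        outdir / "stitched_regions.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(
        [
            {"rank": row["rank"], "signal_score": row["signal_score"]}
            for row in result.hockey["table"]
        ]
    ).to_csv(outdir / "hockey_stick.tsv", sep="\t", index=False, float_format="%.6g")
    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True, default=float) + "\n"
    )
    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.tsv"
    }
    with open(outdir / "manifest.tsv", "w") as fh:
        for name, digest in sorted(manifest.items()):
            fh.write(f"{name}\t{digest}\n")
    return manifest
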