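# rosette

Regulatory-element classification, super-enhancer calling and
overlap-enrichment statistics for ATAC-seq and CUT&RUN peak data.

`rosette` is for analysts who already have peak calls (MACS2-style BED /
narrowPeak files), fragment BED files and a differential-accessibility
table, and need the downstream regulatory-genomics layer as tested,
reusable code:

* **replicate consensus** — keep peaks supported by ≥ 2 replicates per
  condition, then combine conditions into a peak universe;
* **differential filtering** — select decreased ("remodeler-dependent")
  accessible sites at FDR < 0.05 and linear fold change < −1.5;
* **TSS annotation** — nearest-gene assignment, signed center-to-TSS
  distances, log-decade distance bins, proximal/distal classification;
* **promoter/enhancer classification** from histone-mark co-occurrence
  (H3K4me3+H3K27ac at a site → promoter; H3K27ac+H3K4me1 without
  H3K4me3 and > 1 kb from every TSS → enhancer);
* **super-enhancer calling** — stitch enhancers within 12.5 kb, score
  each stitched region by input-subtracted CPM-normalized signal, rank,
  and call everything past the slope-1 tangent of the scaled
  rank-signal ("hockey-stick") curve;
* **overlap statistics** — exact hypergeometric enrichment,
  Benjamini–Hochberg adjustment, UpSet-style multiway overlap counts,
  and binned signal metaprofiles (100 bp bins, ±2 kb) around site
  centers;
* **synthetic data** — a seeded generator that plants promoters,
  typical enhancers, super-enhancer clusters and
  accessibility-dependent sites in a toy genome with
  negative-binomial replicate noise, so every stage can be validated
  against known ground truth.

## The statistics at the core

**Super-enhancer cutoff.** Stitched regions are sorted ascending by
score *s*; with rank *i* of *n*, both axes are scaled to [0, 1]
(*x<sub>i</sub>* = *i*/*n*, *y<sub>i</sub>* = *s<sub>i</sub>*/*s<sub>max</sub>*
after shifting the minimum to zero when negative scores exist).  The
cutoff is the point where a line of slope 1 is tangent to the curve
from below — the index minimizing *y<sub>i</sub>* − *x<sub>i</sub>* —
and regions strictly past it in both rank and score are
super-enhancers.  For a perfectly linear curve the slope never exceeds
1 and nothing is called.

**Overlap enrichment.** For a universe of *N* items of which *K* are
in set A and *n* in set B, the probability of observing ≥ *k* in both
is the upper hypergeometric tail P(X ≥ k), X ~ Hypergeom(N, K, n),
evaluated exactly in log space.  Multiple tests are adjusted by the BH
step-up rule adj₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j.

All interval arithmetic is 0-based half-open (BED convention);
"overlap" always means ≥ 1 shared base unless configured otherwise.

## Worked example

```python
from rosette import SyntheticConfig, generate, run_pipeline

bundle = generate(SyntheticConfig(seed=1))   # 15 Mb toy genome
result = run_pipeline(bundle)
for k in ("n_consensus_peaks", "n_decreased_sites", "n_enhancers",
          "n_stitched_regions", "n_superenhancers", "se_cutoff_score",
          "se_decreased_fraction"):
    print(f"{k}: {result.summary[k]}")
```

prints

```
n_consensus_peaks: 153
n_decreased_sites: 51
n_enhancers: 69
n_stitched_regions: 48
n_superenhancers: 8
se_cutoff_score: 1316.7836084660416
se_decreased_fraction: 0.75
```

Reading: the three control + three treatment ATAC replicates collapse
to a universe of 153 consensus peaks, 51 of which pass the decreased
FDR/fold gates.  The 69 histone-classified enhancers (40 isolated
ones plus 29 super-enhancer constituents) stitch into 48 regions; the
8 regions past the tangent cutoff (input-subtracted score > 1317 CPM)
are exactly the 8 planted super-enhancer clusters, and 75 % of them
overlap a decreased accessible site — the planted dependence
fraction.

The same run is available from a shell:

```bash
rosette simulate --seed 1 --out bundle/
rosette run --bundle bundle/ --out results/
rosette se-call --enhancers enh.bed --treatment h3k27ac_frags.bed \
        --control input_frags.bed --out se.tsv
rosette enrich --universe-n 10 --set-a-n 5 --set-b-n 4 --overlap-k 3
rosette profile --sites sites.bed --fragments frags.bed --out prof.tsv
```

## Layout

```
src/rosette/
  intervals.py       interval model, set algebra, BED/narrowPeak I/O
  peaks.py           replicate consensus, differential filtering
  annotation.py      nearest-TSS assignment and distance binning
  elements.py        promoter/enhancer classification
  superenhancers.py  stitching, scoring, tangent cutoff
  enrichment.py      hypergeometric / BH / multiway overlaps / profiles
  simulate.py        seeded synthetic-genome generator
  pipeline.py, cli.py  orchestration and the `rosette` command
docs/methods.md      model assumptions, parameter choices, limitations
```
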