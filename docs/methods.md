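# Methods

## Scope and coordinate conventions

`rosette` operates strictly downstream of peak calling: its inputs are
peak intervals (BED3/5/6 or ENCODE narrowPeak), fragment-span BED
files, a gene table (one TSS per row) and a per-peak differential
table (log2 fold change, FDR).  Read alignment, peak calling and the
count-model fit that produces the differential table are out of
scope; the differential table is consumed as given (or simulated, see
below).

All coordinates are 0-based half-open.  Two intervals overlap when
they share at least one base; book-ended intervals share none.
Chromosome names are compared as exact strings — no silent "chr"
aliasing (an explicit `normalize_chrom_names` helper exists for
callers who need it).  Peaks are treated as unstranded; gene strand is
used only to sign TSS distances.

## Replicate consensus and the peak universe

Peaks from all replicates of a condition are pooled and clustered by
single-linkage ≥ 1 bp overlap.  A cluster is retained when members
from at least `min_support` (default 2) distinct replicates
contribute, and the retained coordinate is the cluster's union span —
a deliberately conservative choice that never truncates a replicate's
evidence; users comparing against intersection-style consensus peaks
should expect slightly wider intervals.  Per-condition consensus sets
are merged at gap 0 into the combined universe used for counting and
as the hypergeometric universe for interval-level enrichment.

## Differential filtering

The decreased ("dependent") site list applies two strict gates:
FDR < `fdr_max` (default 0.05) and linear fold change ≤ −`fold_min`
(default 1.5, i.e. log2FC ≤ −0.585).  The fold threshold is
interpreted on the linear scale because upstream count models
conventionally report linear fold values in this convention; a
`fold_scale="log2"` switch applies the number to log2FC directly, and
`fold_min=None` disables the fold gate (the FDR-only site lists used
for overlap analyses).  Relaxing either gate can only grow the
selected set, and the decreased/increased selections are disjoint by
construction — both are tested properties.

## TSS annotation

Distance is measured from the peak center, `floor((start+end)/2)`, to
the nearest TSS on the same chromosome, ties broken to the
lexicographically smallest gene id.  Gene-body membership is ignored:
a peak inside a long gene but far from its TSS is annotated by TSS
distance, the convention of the common annotation tools this module
mirrors.  Distance bins default to the log-decade edges 1/10/100 kb.
"Proximal" means within 1 kb inclusive; distal is strictly more than
1 kb.  Multi-isoform genes must be flattened to one row per TSS by
the caller; the module deliberately keeps one-TSS-per-record
semantics.

## Promoter/enhancer classification

Mark presence is a binary ≥ 1 bp overlap of a candidate site with the
mark's peak set.  A candidate is a *promoter* when it carries both
H3K4me3 and H3K27ac, an *enhancer* when it carries H3K27ac and
H3K4me1, no H3K4me3, and sits more than 1 kb from every TSS.
Everything else — including H3K27ac-only and H3K4me1-only sites — is
left unclassified rather than given an invented class.  The candidate
universe defaults to the H3K27ac peak set since both positive rules
require H3K27ac.  A signal-ratio ("relatively lacking H3K4me3")
variant would be a natural extension; the binary peak-overlap rule is
the default because it is auditable against peak files alone.

## Super-enhancer calling

Enhancer-class sites are stitched transitively whenever the gap to
the next site is ≤ 12.5 kb.  TSS-proximal constituents are not
re-excluded at the stitching stage: the enhancer definition upstream
already removed promoter-proximal sites.

Each stitched region is scored as

    score = CPM_treatment(region) − CPM_control(region)

where a fragment is counted in a region iff its midpoint lies inside
(unambiguous for edge-spanning fragments), and CPM normalizes by
total library size.  Input subtraction happens after per-library CPM
normalization; the alternative order (subtract raw counts, then
normalize) is not equivalent when library sizes differ and is not
offered.  The control library is whatever the caller designates —
IgG, input chromatin — no assumption is made about its type.
Negative scores (control exceeds treatment) are retained and rank
lowest; before scaling, scores are shifted so the minimum is zero.
An optional flooring of negatives was considered and rejected as a
silent data-dependent filter.

Regions are sorted ascending by score; rank and score are scaled to
[0, 1] and the cutoff is the tangent point of a slope-1 line touching
the curve from below, computed as the index minimizing
`scaled_signal − scaled_rank`.  Ties — exact or within 1e-9 on the
scaled curve, which absorbs floating-point noise in the analytically
linear case — resolve to the highest rank, so tied regions fall on
the non-super side; regions whose score equals the cutoff score are
likewise never super.  Degenerate inputs: fewer than two regions, or
all scores equal after shifting, produce no call (cutoff `None`,
nothing flagged) with a logged warning.

## Enrichment statistics and metaprofiles

The hypergeometric test is exact and evaluated through the log
survival function; the default is the upper tail (enrichment), with a
lower-tail option for depletion.  The universe is always supplied by
the caller and echoed into the result, because the p-value is acutely
sensitive to it: for interval-level tests the combined consensus
universe is the natural choice, for gene-level tests the detected
gene set.  BH adjustment is the standard step-up rule, capped at 1,
returned in input order.

Multiway (2–4 set) overlap tables partition gene sets exactly into
exclusive cells; for interval sets each interval is assigned to the
combination of all sets it overlaps and counts are reported per
source set, because interval overlap counts are asymmetric — one
region may hit several partners.

Metaprofiles count fragment midpoints in 100 bp bins across ±2 kb
around site centers (40 bins by default), convert to CPM, and average
across sites.  No per-site rescaling is applied, so profiles of
disjoint site classes combine as site-count-weighted means — a tested
invariant.

## The synthetic genome

The generator emulates the statistical structure the pipeline
assumes, not real sequence: there is no sequence content, GC bias or
mappability, and fragments are fixed-length (200 bp) spans.  Defaults
were chosen once as a realistic miniature and are not tuned per
experiment:

| parameter | default | meaning |
|---|---|---|
| genome | 5 × 3 Mb | placement grid of 150 × 100 kb blocks |
| genes | 60 | one TSS per 100 kb block, ≥ 40 kb apart |
| typical enhancers | 40 | H3K27ac+H3K4me1, > 1 kb from every TSS |
| SE clusters | 8 | 3–5 constituents, gaps drawn U[1, 12] kb |
| SE signal multiplier | 10× | H3K27ac fragment excess per constituent |
| fragment mean | 60 / element | Poisson fragment counts, uniform midpoints |
| replicates | 3 per condition | ATAC peak sets with 0.95 detection, ±50 bp jitter |
| NB dispersion | 0.05 | replicate count noise, var = μ + αμ² |
| baseline ATAC count | 150 | per-site per-replicate mean |
| dependent fraction | 0.75 | of typical enhancers and of SE clusters |
| planted log2FC | −2 | treatment mean scaled by 2^−2 at dependent sites |

One element group per 100 kb block with 20 kb margins guarantees
structurally that (a) no enhancer lies within 1 kb of a TSS, (b)
distinct groups are ≥ 40 kb apart so 12.5 kb stitching can never
bridge them, and (c) every planted cluster stitches into exactly one
region (intra-cluster gaps < 12.5 kb).  These guarantees are what
make planted-recovery tests exact; they also mean the generator does
not exercise the genuinely ambiguous layouts of real genomes
(enhancers straddling the 1 kb boundary, clusters separated by
≈ 12.5 kb), so passing recovery tests demonstrates correctness of the
machinery, not robustness to boundary-adjacent biology.

The differential table is produced by a synthetic stand-in for an
upstream count-model fit: negative-binomial replicate counts per
condition, a Wald test on the log2 fold change with a delta-method
standard error using the generating dispersion (shared across sites,
mirroring the information sharing of dispersion-moderated models),
and BH adjustment.  Its empirical FDR on null sites is checked in the
suite.  With `noise=False` every stochastic draw becomes
deterministic and the table carries the planted effects exactly,
giving noise-free recovery fixtures.

All randomness flows from one `numpy.random.default_rng(seed)`
stream; identical configs reproduce byte-identical output files, and
the pipeline itself is a pure function of its inputs (verified by
sha256 manifests).

## Problem sizes used in validation

The shipped validation runs use the default 15 Mb bundle (~160 ATAC
sites, ~50 k fragments per library), a 40-cluster variant across five
seeds for the dependence-fraction check, 1000-instance randomized
oracle sweeps for the interval algebra, an exhaustive hypergeometric
sweep over universes up to N = 12 plus a 10⁶-draw Monte-Carlo check,
and 100 seeded instances for the super-enhancer analytic limits.
These sizes keep the whole suite under a minute of compute while
leaving every oracle comparison exact.

## Known limitations

* The enhancer rule is binary peak overlap; no signal-ratio mode yet.
* One TSS per gene record; isoform-aware annotation is the caller's
  responsibility.
* Venn/UpSet counts for interval sets depend on direction (per source
  set); there is no canonical symmetric count, and both directions
  are reported rather than picking one.
* The synthetic differential stand-in is not a replacement for a real
  count-model fit and is labelled as synthetic wherever it appears.
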