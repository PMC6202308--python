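# Methods

This note documents the models, conventions and design choices behind
`chorseq`: what the pipeline computes, what the simulator assumes, and what
passing tests do and do not establish.

## Coordinates and formats

All coordinates are 0-based half-open `[start, end)` (BED convention)
throughout; 1-based display would be formatting only. "Overlap" always
means ≥ 1 bp of intersection under half-open arithmetic unless a larger
`min_overlap` is requested. Parsers (BED3–6, ENCODE narrowPeak/broadPeak,
bedGraph, chrom-sizes) are strict: wrong column counts, inverted intervals
and unknown chromosomes are errors with line numbers; skip-with-warning for
unknown chromosomes is opt-in. Parsers never reorder records. Peak q-values
are kept as stored in the file (conventionally −log10); the
replicated-region q-value filter exposes its comparison direction because
published pipelines disagree — the default keeps significant (q ≤ cutoff)
regions.

Spike-in reads are recognised purely by chromosome-name membership in the
spike-in genome layout, mirroring dual-genome alignment; target and
spike-in layouts must have disjoint chromosome names.

## Coverage model

Single-end reads are extended from their 5′ alignment end to the mean
library fragment size (default 250 bp for narrow marks, 500 bp for broad)
in the strand direction, clipped at chromosome ends. A bin counts every
extended read overlapping it by ≥ 1 bp (occupancy-style counting — not
fractional, not midpoint — which is what an extended-read coverage track
measures and what a per-base brute-force oracle can verify). The trailing
bin of a chromosome keeps its natural shorter width and is flagged.
Deduplication is assumed done upstream; the pipeline never deduplicates.

Normalizations:

* `RPM` = count × 1e6 / target-genome unique reads;
* `RRPM` = count × 1e6 / spike-in unique reads (requires > 0 spike-in
  reads — the error message names the precondition);
* `RPKM` = count × 1e9 / (region length × target reads) for region-level
  quantitation;
* `percent_of_max` divides by the maximum of the *displayed* vector (one
  locus, one anchor matrix — never genome-wide) and multiplies by 100, so
  the maximum maps to exactly 100.0 in floating point; an all-zero input
  raises a `ZeroMaxWarning`;
* `zscore` standardizes with the population (divide-by-n) standard
  deviation by default (`ddof` configurable); constant vectors are an
  error.

## Window universe

Parental peaks are tiled from their start into non-overlapping windows of
exactly the window size (25 bp / 500 bp / 2 kb depending on analysis);
trailing remainders are dropped rather than emitted short so windows stay
size-comparable. Only windows overlapping replicated-region calls enter any
downstream analysis. Windows must sit on the coverage bin grid so that a
window's signal is an exact sum of bins (equivalently, re-binning the reads
at window size — identical by construction).

## Displacement of recycled peaks

Parental and nascent peak sets are matched by *unique* mutual overlap: a
pair is kept only when the parental peak overlaps exactly one nascent peak
and vice versa. Each input list must be internally non-overlapping. Per
pair we record |Δstart| and |Δend|; the headline statistic is the per-pair
mean of the two end distances, but both per-end vectors are kept so the
pooled convention is recoverable. For a coherent Gaussian shift of sd σ the
expected mean per-end distance is σ·√(2/π).

## Restoration and loss classifiers

Given a window's RRPM levels across a chase, its category is the earliest
timepoint *t* with `final / level(t) ≤ 1.5` (the final timepoint trivially
qualifies, so every window with non-zero final signal is classified; zero
final signal is counted and reported, never silently dropped). Boundary
conventions are explicit and configurable: the threshold itself counts as
restored (≤), and the moderate loss band is closed `[1.5, 3]`. A `strict`
mode implements the literal alternative reading in which windows whose
ratios never exceed the threshold (immediately-restored `R0` windows) are
discarded a priori; the default is the permissive reading, since an `R0`
class is a meaningful outcome. The final reference is the last *measured*
timepoint, not a fitted asymptote, and no continuous kinetic fitting is
attempted — the classifier is deliberately discrete.

Calls are made per replicate; only windows with identical categories in
both replicates are retained (`replicate_concordance`, which also reports
the retained fraction). Category proportions are computed over classified,
concordant windows and sum to 1. The classifiers are scale-free
(multiplying a window's trajectory by c > 0 cannot change its category) and
monotone (raising an earlier level can only move the category earlier).

## Profiles and Hilbert images

Anchor profiles snap each anchor (domain-border position or interval
midpoint) to the nearest bin boundary and take `2·flank/bin` columns;
anchors whose flanks leave the chromosome are dropped, not clipped, to keep
the matrix rectangular (dropped counts reported). Oriented anchors are
flipped so domain interior / downstream is always to the right.
Length-normalized (metagene) profiles resample each body onto a fixed
number of pseudo-bins by exact bp-weighted means — mean pooling, not sums,
because normalized signal is density-like — which conserves the body mean
and makes identically-shaped bodies of different lengths identical after
resampling. Heatmap scaling is percent-of-max per sample and idempotent.

The Hilbert mapping uses the classic iterative index→(x, y) algorithm with
a fixed, documented orientation: origin at the lower-left cell, first step
along +y, grids indexed `[y, x]`. Published tools differ in this
convention; it only rotates/reflects the image. Inputs are mean-pooled
(longer) or zero-padded (shorter, flagged) to 4^order cells. Bijectivity
and 4-neighbour adjacency of consecutive indices are verified exhaustively
for orders 1–6 in the tests.

## The simulator

`synthetic_data` forward-simulates the biology the analysis assumes:

* **Landscape** — narrow peaks and/or broad domains placed without overlap
  by the uniform-spacings construction (free space split among gaps by
  normalized exponentials, with an optional guaranteed minimum gap);
  coordinates are snapped to the analysis bin grid so windows tile features
  exactly. Per-feature parental levels are lognormal (CV 0.3 by default)
  around 1. Replicated tracts cover a configured fraction of the genome in
  fixed-size regions.
* **Kinetics** — restoration is a *step*: each feature's level is
  `L·(dilution + (1−dilution)·[t ≥ plateau])`, with plateau times assigned
  per feature over the chase timepoints (balanced cyclic assignment by
  default, so any contiguous subset of the genome keeps near-equal category
  shares; explicit proportions use largest-remainder quotas so rare classes
  are represented exactly). A step is the right ground truth for a discrete
  earliest-timepoint classifier; an exponential mode (τ = plateau/2) exists
  for robustness checks. Inhibitor mode freezes levels at the nascent
  (recycled) value and erodes them to a per-feature target fold at the
  final timepoint.
* **Recycling displacement** — recycled (parental-derived) fragments are
  jittered by a centred Gaussian of sd `displacement_sigma` (default
  100 bp); the restored (new-histone) fraction is not. For the
  peak-displacement study the kernel acts coherently: whole nascent peaks
  are shifted by one draw each, preserving width.
* **Sequencing** — each library draws Poisson totals from the chromatin
  composition: target and spike-in expected reads split the configured
  depth in proportion to their chromatin mass, with the spike-in mass a
  fixed fraction (5%) of the parental target mass. The spike-in read share
  therefore falls as target signal is restored — exactly the effect RRPM
  corrects. Optional extra lognormal noise of a given CV (default 10%,
  mean-1) is applied per feature per library. Read 5′ positions are drawn
  from the piecewise-constant density; background (non-feature) density is
  non-zero so zero-signal edge cases are exercised.
* **Determinism** — every random stream derives from
  `SeedSequence([seed, stage, replicate, timepoint])`, so any library can
  be regenerated in isolation and identical configs give identical output
  bytes.

`naive_domain_caller` (threshold runs of bins, single-bin gaps merged,
minimum width) is a fixture-grade helper only; real data is expected to
arrive as MACS output files.

## Study designs and problem sizes

The bundled studies (in `chorseq.studies`, driven by `analysis/`) choose
sizes that keep a full run on one CPU in minutes:

* **Restoration recovery** — 1 Mb genome, 1000 peaks of 500 bp (= 1000
  windows), four timepoints × two replicates, 1.2e6 reads/library (~1e3
  reads per fully-restored window). The depth was fixed by a power
  analysis: with the 10% per-measurement CV, the final/level(t) log-ratio
  noise floor is ~0.14, and below ~1e3 reads/window counting noise pushes
  the misclassification rate to where recovered category proportions are no
  longer estimable to a few points. Peaks are ≥ 450 bp apart (more than
  the read extension) and background is 1% of peak density so windows
  measure their own locus.
* **Normalization contrast** — 200 peaks, all restoring at the final
  timepoint, displacement off: isolates the normalization behaviour from
  recycling geometry.
* **Inhibitor loss** — 150 broad domains of 8 kb (2 kb windows), loss
  classes at 96 / 3.5 / 0.5% with target folds 1.1 / 2 / 4.
* **Displacement** — 1000 peaks of 1 kb with ≥ 1.2 kb gaps (so ±σ shifts
  cannot create overlaps), σ = 100 bp plus a σ = 0 control.

## What the synthetic data does not show

The simulator emulates flat-top features, uniform fragment sampling, exact
replication tracts and a perfectly constant spike-in ratio. It does not
model fragment-size distributions, GC or mappability bias, duplicate reads,
alignment errors, antibody efficiency differences between samples, or
partially-replicated windows within a labeling pulse. Passing recovery
tests therefore demonstrates that the *analysis* is correct and unbiased
under its own assumptions at realistic depths — not that those assumptions
hold for any particular real library. Peak calling itself (MACS) is out of
scope and consumed via files.

## Known limitations

* `assemble_timecourse` requires windows on the bin grid; arbitrary-offset
  windows would need re-binning from reads.
* The restoration classifier is sensitive to the final-timepoint value (it
  is the reference for every ratio); a noisy final measurement propagates
  into all categories. Replicate concordance is the only guard.
* `bigWig` output and input-subtraction normalization are not implemented;
  tracks are exchanged as bedGraph.
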