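# chorseq

Quantitative analysis of histone-PTM occupancy on newly replicated DNA
(ChOR-seq / qChOR-seq style experiments), plus a forward simulator of the
underlying chromatin-replication biology that provides ground truth for
every stage of the analysis.

## The problem

When a replication fork passes, parental nucleosomes carrying
post-translational modifications (e.g. H3K4me3, H3K27me3) are recycled onto
the daughter strands and mixed ~1:1 with new, unmodified histones. Two
quantitative questions follow:

1. **Position** — how far from its pre-replication position does a recycled,
   modified nucleosome land? Measured here as the absolute start/end
   coordinate distances between uniquely-overlapping parental and nascent
   peak calls.
2. **Kinetics** — how quickly is the two-fold dilution of each mark
   "restored" by de novo modification, locus by locus? Measured on a chase
   time course (e.g. T0/T1/T6/T12 h after replication) as the earliest
   timepoint *t* at which a window's level is within 1.5-fold of its final
   level: category `R0` restores immediately, `R12` only by 12 h.

Question 2 is only answerable with an **exogenous spike-in**: sequencing
depth is arbitrary per library, so reads-per-million (RPM) hides global
gains. With constant spike-in chromatin, scaling each bin count by
1e6 / (spike-in unique reads) gives **reference-adjusted RPM (RRPM)**,
which preserves between-sample level differences:

    RPM_i  = c_i * 1e6 / N_target
    RRPM_i = c_i * 1e6 / N_spikein

where `c_i` is the count of extended reads overlapping bin *i*. All
occupancy comparisons are restricted to replicated DNA (windows of parental
peaks that overlap replicated-region calls), and loss of signal under
methyltransferase inhibition is binned by the T0/T24 fold change
(<1.5 low, 1.5–3 moderate, >3 high).

The package is organised as a library (`src/chorseq/`: I/O for BED /
narrowPeak / broadPeak / bedGraph dialects, binning and normalization,
interval algebra, the kinetic classifiers, profile/Hilbert visualisation,
and the simulator), a `chorseq` CLI orchestrating the stages, and numbered
analysis drivers under `analysis/` that run the simulated studies and write
tables under `results/`.

## Worked example

The restoration-kinetics study simulates 1000 parental 500 bp peaks on a
1 Mb genome with balanced true plateau categories, sequences two replicate
four-timepoint chases with a constant spike-in genome, and runs the full
measurement pipeline back over the reads:

```
$ python analysis/04_restoration_kinetics.py --seed 1
1000 replicated peak windows; 936 concordant across replicates (93.6%).
Concordant-call accuracy vs truth: 99.9%; max category-proportion error 2.03 points.
Recovered proportions: T0=26.5%, T1=25.9%, T6=24.7%, T12=23.0%
```

936/1000 windows get the same category in both replicates; of those, 99.9%
match the category the simulator actually assigned, and the recovered
category proportions sit within ~2 points of the programmed 25/25/25/25.

```
$ python analysis/02_peak_displacement.py --seed 1
sigma=100 bp: 1000 unique pairs, mean per-end displacement 81.9 bp (analytic 79.8 bp), ...
```

With a Gaussian recycling kernel of sigma = 100 bp, the measured mean
per-end peak displacement (81.9 bp) matches the analytic expectation
sigma·sqrt(2/pi) = 79.8 bp.

```
$ python analysis/03_rpm_vs_rrpm.py --seed 1
Pooled final/T0 signal ratio over 200 windows:
  RPM  : 1.015  (blind to the gain)
  RRPM : 1.964  (programmed gain 1/dilution = 2.0)
```

The same libraries, normalized both ways: depth-relative RPM reports no
change across a chase in which every locus doubles, while spike-in-anchored
RRPM recovers the programmed two-fold gain.

The other drivers: `01` (landscape summary), `05` (inhibitor loss classes),
`06` (domain-border profiles and a Hilbert-curve grid).

## CLI

`chorseq all --config configs/demo.yaml --out OUTDIR` simulates and runs
the whole analysis (deterministic given the config seed; re-runs are
byte-identical). Individual stages — `simulate`, `bin`, `normalize`,
`windows`, `classify`, `loss`, `distance`, `profile`, `hilbert` — compose
to the same result; each writes a `manifest.json` with config and input
digests. Config keys mirror `SimulationConfig` fields under `simulation:`
plus `classify: {fold_threshold}`, `loss: {low_cut, high_cut}`; see
`configs/demo.yaml`.

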