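"""End-to-end simulated studies: each function forward-simulates an
experiment with :mod:`chorseq.synthetic_data`, runs the *measurement-side*
pipeline (extend -> bin -> spike-in normalize -> window -> classify) exactly
as it would run on real libraries, and compares the outcome with the
simulator's ground truth.

These are the computations the numbered ``analysis/`` scripts narrate and the
acceptance checks re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import coverage, profiles, regions, restoration
from .genomic_io import GenomeLayout, LibraryCounts, split_by_genome
from .regions import WindowSet
from .restoration import TimeCourse
from .synthetic_data import (
    Landscape,
    SimulationConfig,
    displaced_peaks,
    simulate_landscape,
    simulate_library,
)

__all__ = [
    "recovery_config",
    "library_to_tracks",
    "windows_from_landscape",
    "assemble_replicate",
    "RecoveryResult",
    "run_restoration_recovery",
    "run_displacement_study",
    "LossResult",
    "run_loss_study",
    "run_border_profile_study",
]


def recovery_config(seed: int, **overrides) -> SimulationConfig:
    """The restoration parameter-recovery study design: 1 Mb genome, 1000
    parental 500 bp peaks (= 1000 windows) with balanced plateau categories,
    fully replicated labeling, 2 replicates.

    Peaks are separated by at least 450 bp (more than the 250 bp read
    extension) and background is kept at 1% of peak density so window sums
    measure their own locus; the 1.2e6-read depth puts ~1e3 reads in a fully
    restored window, below which (power analysis) the 10% measurement CV no
    longer dominates category-proportion recovery.
    """
    base = dict(
        seed=seed,
        n_peaks=1000,
        replicated_fraction=1.0,
        min_gap=450,
        background_level=0.01,
        depth=1_200_000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def library_to_tracks(
    lib, landscape: Landscape, bin_size: Optional[int] = None
) -> tuple[coverage.BinnedTrack, coverage.BinnedTrack, LibraryCounts]:
    """Run one library through the measurement pipeline.

    Returns (RPM track, RRPM track, library counts): reads are split by
    genome of origin, target reads extended to the configured fragment size
    and counted into bins, then normalized both ways.
    """
    cfg = landscape.config
    bin_size = bin_size if bin_size is not None else cfg.bin_size
    target_reads, spike_reads = split_by_genome(
        lib.reads, landscape.target_layout, landscape.spikein_layout
    )
    counts = LibraryCounts(len(target_reads), len(spike_reads))
    extended = coverage.extend_reads(
        target_reads, cfg.read_extension, landscape.target_layout
    )
    raw = coverage.bin_counts(extended, bin_size, landscape.target_layout)
    return coverage.rpm(raw, counts), coverage.rrpm(raw, counts), counts


def windows_from_landscape(landscape: Landscape) -> WindowSet:
    """Parental-peak windows restricted to replicated DNA (the analysis
    universe of the restoration studies)."""
    cfg = landscape.config
    features = landscape.peaks if landscape.peaks else landscape.domains
    tiled = regions.tile_peaks(features, cfg.window_size, source_id="parental")
    return regions.filter_by_overlap(tiled, landscape.replicated, region_id="replicated")


def assemble_replicate(
    landscape: Landscape,
    replicate: int,
    windows: WindowSet,
    normalization: str = "RRPM",
) -> TimeCourse:
    """Simulate and assemble one replicate's full time course matrix."""
    cfg = landscape.config
    tracks = []
    lib_counts = []
    for ti, (label, hours) in enumerate(cfg.timepoints):
        lib = simulate_library(landscape, replicate, ti)
        rpm_tr, rrpm_tr, counts = library_to_tracks(lib, landscape)
        tracks.append((label, hours, rrpm_tr if normalization == "RRPM" else rpm_tr))
        lib_counts.append(counts)
    return restoration.assemble_timecourse(
        tracks,
        windows,
        mark="simulated",
        replicate=f"rep{replicate + 1}",
        library_counts=lib_counts,
    )


@dataclass
class RecoveryResult:
    """Outcome of the restoration parameter-recovery study."""

    n_windows: int
    n_concordant: int
    retained_fraction: float
    accuracy: float  # concordant windows matching simulated truth
    proportions: dict[str, float]  # recovered, over concordant windows
    true_proportions: dict[str, float]  # truth, over the same window universe
    max_proportion_error: float  # max |recovered - true| over categories
    rrpm_final_t0_ratio: float
    rpm_final_t0_ratio: float
    timecourses: list = field(default_factory=list, repr=False)


def run_restoration_recovery(
    seed: int,
    cfg: Optional[SimulationConfig] = None,
    strict: bool = False,
    keep_timecourses: bool = False,
) -> RecoveryResult:
    """Full restoration analysis on simulated data with known kinetics.

    Simulates ``cfg.replicates`` replicate time courses, classifies each
    window per replicate, intersects replicates, and scores calls against the
    simulator truth. Also measures the RPM-vs-RRPM contrast: with equal
    sequencing depth per timepoint, depth-relative RPM is blind to the
    programmed two-fold restoration gain while spike-in-anchored RRPM reports
    it (final/T0 expectation = 1/dilution).
    """
    if cfg is None:
        cfg = recovery_config(seed)
    landscape = simulate_landscape(cfg)
    windows = windows_from_landscape(landscape)
    truth_of = dict(zip([f.name for f in landscape.features], landscape.categories))
    labels = [lab for lab, _ in cfg.timepoints]

    calls_by_rep = []
    rrpm_tcs = []
    rpm_sums = np.zeros(2)  # (T0, final) pooled over windows, rep1 RPM
    rrpm_sums = np.zeros(2)
    for rep in range(cfg.replicates):
        tc_rrpm = assemble_replicate(landscape, rep, windows, "RRPM")
        rrpm_tcs.append(tc_rrpm)
        result = restoration.classify_restoration(tc_rrpm, strict=strict)
        if result.n_unclassifiable:
            raise RuntimeError(
                f"{result.n_unclassifiable} windows had zero final signal at "
                f"this depth; the study design should not produce any"
            )
        calls_by_rep.append(result.calls)
        if rep == 0:
            tc_rpm = assemble_replicate(landscape, rep, windows, "RPM")
            rpm_sums[:] = tc_rpm.matrix[:, 0].sum(), tc_rpm.matrix[:, -1].sum()
            rrpm_sums[:] = tc_rrpm.matrix[:, 0].sum(), tc_rrpm.matrix[:, -1].sum()

    conc = restoration.replicate_concordance(calls_by_rep[0], calls_by_rep[1])
    correct = sum(
        1 for c in conc.calls if c.category == truth_of[c.window.name]
    )
    props = restoration.category_proportions(conc.calls, order=labels)
    true_counts = {lab: 0 for lab in labels}
    for w in windows:
        true_counts[truth_of[w.name]] += 1
    true_props = {lab: true_counts[lab] / len(windows) for lab in labels}
    max_err = max(abs(props[lab] - true_props[lab]) for lab in labels)

    return RecoveryResult(
        n_windows=len(windows),
        n_concordant=len(conc.calls),
        retained_fraction=conc.retained_fraction,
        accuracy=correct / len(conc.calls),
        proportions=props,
        true_proportions=true_props,
        max_proportion_error=max_err,
        rrpm_final_t0_ratio=float(rrpm_sums[1] / rrpm_sums[0]),
        rpm_final_t0_ratio=float(rpm_sums[1] / rpm_sums[0]),
        timecourses=rrpm_tcs if keep_timecourses else [],
    )


def run_normalization_contrast(seed: int, **overrides) -> dict:
    """The RPM-vs-RRPM contrast on a uniformly restoring landscape.

    Every locus is programmed to restore at the final timepoint, so between
    T0 and the final chase the entire signal doubles while per-timepoint
    sequencing depth stays constant. Depth-relative RPM then cannot see the
    gain (pooled final/T0 ratio ~ 1) while spike-in-anchored RRPM reports it
    (ratio ~ 1/dilution). Pooled ratios over all peak windows are returned.
    """
    base = dict(
        seed=seed,
        target_chroms={"chr1": 400_000},
        n_peaks=200,
        replicated_fraction=1.0,
        min_gap=450,
        background_level=0.005,
        displacement_sigma=0.0,  # recycling geometry is irrelevant here
        depth=250_000,
    )
    base.update(overrides)
    cfg = SimulationConfig(**base)
    final_label = cfg.timepoints[-1][0]
    cfg.category_probs = {final_label: 1.0}
    landscape = simulate_landscape(cfg)
    windows = windows_from_landscape(landscape)
    sums = {}
    for norm in ("RPM", "RRPM"):
        tc = assemble_replicate(landscape, 0, windows, norm)
        sums[norm] = (tc.matrix[:, 0].sum(), tc.matrix[:, -1].sum())
    return {
        "n_windows": len(windows),
        "dilution": cfg.dilution,
        "expected_rrpm_ratio": 1.0 / cfg.dilution,
        "rpm_final_t0_ratio": float(sums["RPM"][1] / sums["RPM"][0]),
        "rrpm_final_t0_ratio": float(sums["RRPM"][1] / sums["RRPM"][0]),
    }


def run_displacement_study(
    seed: int,
    sigma: float = 100.0,
    n_peaks: int = 1000,
) -> dict:
    """Parental -> nascent peak displacement under coherent recycling.

    Nascent peaks are parental peaks shifted by one Gaussian draw each
    (sd ``sigma``); uniquely overlapping pairs are matched and their per-end
    distances summarized. The analytic expectation of the mean per-end
    distance is the mean absolute value of the shift, sigma * sqrt(2/pi).
    """
    cfg = SimulationConfig(
        seed=seed,
        target_chroms={"chr1": 4_000_000},
        n_peaks=n_peaks,
        peak_width=1000,
        min_gap=1200,  # >> sigma so shifted peaks stay non-overlapping
        displacement_sigma=sigma,
    )
    landscape = simulate_landscape(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    nascent = displaced_peaks(
        landscape.peaks, sigma, rng, chrom_lengths=cfg.target_chroms
    )
    pairs = regions.pair_unique_peaks(landscape.peaks, nascent)
    summary = regions.displacement_summary(pairs)
    return {
        "sigma": sigma,
        "n_pairs": len(pairs),
        "mean_per_end_bp": summary.pooled_mean,
        "mean_per_pair_bp": summary.mean,
        "median_per_pair_bp": summary.median,
        "analytic_mean_bp": sigma * np.sqrt(2 / np.pi),
    }


@dataclass
class LossResult:
    n_windows: int
    n_concordant: int
    retained_fraction: float
    accuracy: float
    proportions: dict[str, float]
    true_proportions: dict[str, float]


def run_loss_study(seed: int, cfg: Optional[SimulationConfig] = None) -> LossResult:
    """Signal-loss analysis under simulated methyltransferase inhibition:
    T0 vs T24 fold change of recycled broad-domain signal, binned into
    low/moderate/high loss, intersected across replicates, scored vs truth."""
    if cfg is None:
        cfg = SimulationConfig.inhibitor_like(seed=seed)
    landscape = simulate_landscape(cfg)
    windows = windows_from_landscape(landscape)
    truth_of = dict(zip([f.name for f in landscape.features], landscape.categories))

    calls_by_rep = []
    for rep in range(cfg.replicates):
        tc = assemble_replicate(landscape, rep, windows, "RRPM")
        result = restoration.classify_loss(tc)
        calls_by_rep.append(result.calls)
    conc = restoration.replicate_concordance(calls_by_rep[0], calls_by_rep[1])
    order = ["low", "moderate", "high"]
    props = restoration.category_proportions(conc.calls, order=order)
    correct = sum(1 for c in conc.calls if c.category == truth_of[c.window.name])
    true_counts = {lab: 0 for lab in order}
    for w in windows:
        true_counts[truth_of[w.name]] += 1
    return LossResult(
        n_windows=len(windows),
        n_concordant=len(conc.calls),
        retained_fraction=conc.retained_fraction,
        accuracy=correct / len(conc.calls) if conc.calls else float("nan"),
        proportions=props,
        true_proportions={lab: true_counts[lab] / len(windows) for lab in order},
    )


def run_border_profile_study(seed: int, flank: int = 2000) -> dict:
    """Average RRPM profile around broad-domain borders at T0.

    Borders further than 5 kb from any replicated-region edge are oriented
    (interior to the right) and the nascent-library signal averaged; the
    interior/exterior contrast quantifies how sharply recycled signal stays
    within parental domain boundaries.
    """
    cfg = SimulationConfig.h3k27me3_like(seed=seed)
    landscape = simulate_landscape(cfg)
    anchors = regions.domain_borders(landscape.domains, landscape.replicated)
    lib = simulate_library(landscape, 0, 0)
    _, rrpm_tr, _ = library_to_tracks(lib, landscape)
    mat = profiles.anchor_profile(rrpm_tr, anchors, flank)
    mean = mat.column_means
    half = len(mean) // 2
    outside, inside = float(mean[:half].mean()), float(mean[half:].mean())
    return {
        "n_anchors": len(mat.anchors),
        "n_dropped": mat.n_dropped,
        "mean_profile": mean,
        "positions": mat.positions,
        "outside_mean_rrpm": outside,
        "inside_mean_rrpm": inside,
        "inside_outside_ratio": inside / outside if outside > 0 else float("inf"),
    }
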