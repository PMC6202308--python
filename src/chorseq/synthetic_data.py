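"""Forward simulation of the biology and measurement process the pipeline
assumes.

The generative model, per locus carrying a parental PTM level ``L``:

* replication dilutes the mark two-fold — nascent chromatin carries only
  recycled parental histones, so its expected level is ``dilution * L``
  (dilution 0.5 = the 1:1 mix of old and new histones);
* recycled parental fragments are re-deposited near their pre-replication
  position, displaced by a centered Gaussian of width ``displacement_sigma``;
* restoration is a step: each locus reaches its parental plateau at an
  assigned timepoint (the discrete classifier under test needs exactly this
  ground truth); an exponential mode exists for robustness checks;
* under methyltransferase inhibition levels stay frozen at the nascent value
  and optionally erode by a per-locus fold (low/moderate/high loss);
* an exogenous spike-in genome contributes constant chromatin mass, so the
  spike-in share of each sequenced library calibrates absolute levels;
* sequencing draws Poisson read counts from the chromatin composition at a
  configured total depth, with optional extra per-locus lognormal
  (multiplicative) noise of a given CV.

Everything is deterministic given the config seed; per-library streams are
derived from ``(seed, replicate, timepoint)`` so any library can be
regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import BinnedTrack
from .genomic_io import GenomeLayout, GenomicInterval, LibraryCounts

__all__ = [
    "SimulationConfig",
    "Landscape",
    "Library",
    "TimeCourseSim",
    "simulate_landscape",
    "simulate_timecourse",
    "simulate_library",
    "displaced_peaks",
    "naive_domain_caller",
]


@dataclass
class SimulationConfig:
    """All knobs of one simulated qChOR-seq experiment.

    Defaults describe the narrow-mark (promoter peak) restoration study:
    1 Mb target genome, 1000 non-overlapping 500 bp peaks, 80% of the genome
    replicated in 50 kb tracts, two-fold dilution on replication, recycling
    displacement sigma 100 bp, timepoints T0/T1/T6/T12, two replicates,
    1e6-read libraries with 10% extra multiplicative noise. Depth is set so a
    fully restored peak window collects on the order of 1e3 reads, which the
    classifier needs for category proportions to be estimable to a few
    percent under the 10% noise floor.
    """

    seed: int = 0
    # genomes
    target_chroms: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    spikein_chroms: dict[str, int] = field(default_factory=lambda: {"spike_2L": 100_000})
    # parental landscape
    n_peaks: int = 1000
    peak_width: int = 500
    n_domains: int = 0
    domain_width: int = 20_000
    feature_level: float = 1.0  # mean per-bp parental density inside features
    feature_level_cv: float = 0.3  # lognormal spread of parental levels
    background_level: float = 0.02
    min_gap: int = 0  # guaranteed bp between placed features
    # replication
    replicated_fraction: float = 0.8
    replicated_region_size: int = 50_000
    dilution: float = 0.5
    displacement_sigma: float = 100.0
    # kinetics
    mode: str = "restoration"  # or "inhibitor"
    kinetics: str = "step"  # or "exponential"
    timepoints: list[tuple[str, float]] = field(
        default_factory=lambda: [("T0", 0.0), ("T1", 1.0), ("T6", 6.0), ("T12", 12.0)]
    )
    category_probs: Optional[dict[str, float]] = None  # None -> balanced, cyclic
    loss_probs: dict[str, float] = field(
        default_factory=lambda: {"low": 0.96, "moderate": 0.035, "high": 0.005}
    )
    loss_folds: dict[str, float] = field(
        default_factory=lambda: {"low": 1.1, "moderate": 2.0, "high": 4.0}
    )
    # sequencing
    depth: int = 1_000_000  # expected total reads per library (target + spike-in)
    spikein_mass_fraction: float = 0.05  # spike chromatin mass / parental target mass
    read_length: int = 50
    replicates: int = 2
    noise_cv: float = 0.10  # extra lognormal CV per feature per library
    # downstream-analysis parameters carried in the run manifest
    read_extension: int = 250
    bin_size: int = 25
    window_size: int = 500

    def validate(self) -> "SimulationConfig":
        if not 0 < self.dilution <= 1:
            raise ValueError("dilution must be in (0, 1]")
        if self.displacement_sigma < 0:
            raise ValueError("displacement_sigma must be >= 0")
        if self.depth <= 0 or self.read_length <= 0:
            raise ValueError("depth and read_length must be positive")
        if self.mode not in ("restoration", "inhibitor"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.kinetics not in ("step", "exponential"):
            raise ValueError(f"unknown kinetics {self.kinetics!r}")
        if not 0 <= self.replicated_fraction <= 1:
            raise ValueError("replicated_fraction must be in [0, 1]")
        if self.category_probs is not None:
            if abs(sum(self.category_probs.values()) - 1) > 1e-9:
                raise ValueError("category_probs must sum to 1")
        if abs(sum(self.loss_probs.values()) - 1) > 1e-9:
            raise ValueError("loss_probs must sum to 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        shared = set(self.target_chroms) & set(self.spikein_chroms)
        if shared:
            raise ValueError(f"target and spike-in chromosomes overlap: {shared}")
        return self

    @classmethod
    def h3k27me3_like(cls, **overrides) -> "SimulationConfig":
        """Broad-domain setup: fewer, wider features, 2 kb windows, the
        T0/T4/T10/T24 chase."""
        base = dict(
            target_chroms={"chr1": 2_000_000},
            n_peaks=0,
            n_domains=40,
            domain_width=20_000,
            timepoints=[("T0", 0.0), ("T4", 4.0), ("T10", 10.0), ("T24", 24.0)],
            window_size=2000,
            bin_size=500,
            read_extension=500,
            replicated_region_size=100_000,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def inhibitor_like(cls, **overrides) -> "SimulationConfig":
        """EZH2-inhibitor setup: frozen nascent landscape, T0 vs T24 loss."""
        base = dict(
            mode="inhibitor",
            n_peaks=0,
            n_domains=150,
            domain_width=8_000,
            target_chroms={"chr1": 4_000_000},
            timepoints=[("T0", 0.0), ("T24", 24.0)],
            window_size=2000,
            bin_size=500,
            read_extension=500,
            replicated_region_size=100_000,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class Landscape:
    """The simulated parental state: features with levels and true kinetic
    parameters, replicated tracts, and the genome layouts."""

    config: SimulationConfig
    target_layout: GenomeLayout
    spikein_layout: GenomeLayout
    peaks: list[GenomicInterval]
    domains: list[GenomicInterval]
    replicated: list[GenomicInterval]
    levels: np.ndarray  # per feature (peaks then domains)
    categories: list[str]  # timepoint label (restoration) or loss class
    plateau_hours: np.ndarray  # restoration mode; 0 for inhibitor mode
    loss_folds: np.ndarray  # inhibitor mode; 1 elsewhere

    @property
    def features(self) -> list[GenomicInterval]:
        return self.peaks + self.domains

    @property
    def truth(self) -> pd.DataFrame:
        feats = self.features
        return pd.DataFrame(
            {
                "chrom": [f.chrom for f in feats],
                "start": [f.start for f in feats],
                "end": [f.end for f in feats],
                "name": [f.name for f in feats],
                "parental_level": self.levels,
                "category": self.categories,
                "plateau_hours": self.plateau_hours,
                "loss_fold": self.loss_folds,
                "displacement_sigma": self.config.displacement_sigma,
            }
        )

    def expected_level(self, hours: float) -> np.ndarray:
        """Model expectation of each feature's per-bp density at chase time
        ``hours`` (before measurement noise)."""
        cfg = self.config
        if cfg.mode == "inhibitor":
            final_hours = cfg.timepoints[-1][1]
            nascent = cfg.dilution * self.levels
            if hours <= 0:
                return nascent
            # erosion reaches the per-feature target fold at the final timepoint
            frac = hours / final_hours
            return nascent / self.loss_folds**frac
        if cfg.kinetics == "step":
            restored = hours >= self.plateau_hours
            return self.levels * (cfg.dilution + (1 - cfg.dilution) * restored)
        # exponential approach with tau = plateau/2 (tau 0 -> instant)
        tau = np.maximum(self.plateau_hours / 2.0, 1e-9)
        rise = 1.0 - np.exp(-hours / tau)
        return self.levels * (cfg.dilution + (1 - cfg.dilution) * rise)


@dataclass
class Library:
    """One sequenced library: reads from both genomes plus realized totals."""

    replicate: int
    timepoint: str
    hours: float
    reads: list[GenomicInterval]
    counts: LibraryCounts
    expected_target_reads: float
    expected_spikein_reads: float


def _place_non_overlapping(
    rng: np.random.Generator,
    chrom_length: int,
    widths: Sequence[int],
    min_gap: int,
) -> list[int]:
    """Start positions for non-overlapping features of the given widths,
    uniformly distributed (uniform-spacings construction): the free space
    left after reserving feature mass and minimum gaps is split among the
    n+1 inter-feature gaps by normalized exponentials."""
    n = len(widths)
    if n == 0:
        return []
    mass = int(np.sum(widths))
    free = chrom_length - mass - (n + 1) * min_gap
    if free < 0:
        raise ValueError(
            f"infeasible packing: {n} features of total {mass} bp (+ gaps) "
            f"exceed chromosome length {chrom_length}"
        )
    raw = rng.exponential(size=n + 1)
    gaps = min_gap + free * raw / raw.sum()
    starts = []
    pos = 0.0
    for w, g in zip(widths, gaps):
        pos += g
        starts.append(int(pos))
        pos += w
    return starts


def _assign_categories(
    rng: np.random.Generator, n: int, labels: list[str], probs: Optional[dict[str, float]]
) -> list[str]:
    if probs is None:
        # balanced cyclic assignment: every contiguous subset of features
        # (e.g. the replicated ones) keeps near-equal category shares
        return [labels[i % len(labels)] for i in range(n)]
    # quota (largest-remainder) assignment: category counts match the
    # requested proportions as closely as integers allow even for rare
    # classes, with random placement across features
    p = np.array([probs.get(lab, 0.0) for lab in labels])
    quota = p * n
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts), kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    pool = [lab for lab, c in zip(labels, counts) for _ in range(c)]
    return [pool[i] for i in rng.permutation(n)]


def simulate_landscape(cfg: SimulationConfig) -> Landscape:
    """Place parental features and replicated tracts; draw per-feature levels
    and true kinetic parameters. Deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    target = GenomeLayout(dict(cfg.target_chroms), origin="target")
    spike = GenomeLayout(dict(cfg.spikein_chroms), origin="spikein")
    target.check_disjoint(spike)

    chroms = list(cfg.target_chroms)
    lengths = np.array([cfg.target_chroms[c] for c in chroms], dtype=float)
    # features spread over chromosomes proportional to length
    n_feat = cfg.n_peaks + cfg.n_domains
    widths = [cfg.peak_width] * cfg.n_peaks + [cfg.domain_width] * cfg.n_domains
    kinds = ["peak"] * cfg.n_peaks + ["domain"] * cfg.n_domains
    order = rng.permutation(n_feat) if cfg.n_peaks and cfg.n_domains else np.arange(n_feat)
    per_chrom = rng.multinomial(n_feat, lengths / lengths.sum()) if n_feat else []
    peaks: list[GenomicInterval] = []
    domains: list[GenomicInterval] = []
    fi = 0
    for ci, chrom in enumerate(chroms):
        idxs = list(order[fi : fi + per_chrom[ci]]) if n_feat else []
        fi += per_chrom[ci] if n_feat else 0
        ws = [widths[i] for i in idxs]
        starts = _place_non_overlapping(rng, cfg.target_chroms[chrom], ws, cfg.min_gap)
        for i, s in zip(idxs, starts):
            # snap to the analysis bin grid so fixed-width windows tile
            # features exactly (feature widths are grid multiples)
            s = (s // cfg.bin_size) * cfg.bin_size
            iv = GenomicInterval(chrom, s, s + widths[i], name=f"{kinds[i]}_{i + 1:05d}")
            (peaks if kinds[i] == "peak" else domains).append(iv)
    # truth arrays below are indexed in peaks+domains order
    feats = peaks + domains
    n_feat = len(feats)

    sigma_log = np.sqrt(np.log(1 + cfg.feature_level_cv**2))
    levels = cfg.feature_level * np.exp(
        rng.normal(-sigma_log**2 / 2, sigma_log, n_feat)
    )
    labels = [lab for lab, _ in cfg.timepoints]
    hours_of = dict(cfg.timepoints)
    if cfg.mode == "restoration":
        categories = _assign_categories(rng, n_feat, labels, cfg.category_probs)
        plateau = np.array([hours_of[c] for c in categories])
        folds = np.ones(n_feat)
    else:
        loss_labels = list(cfg.loss_probs)
        categories = _assign_categories(rng, n_feat, loss_labels, cfg.loss_probs)
        plateau = np.zeros(n_feat)
        folds = np.array([cfg.loss_folds[c] for c in categories])

    # replicated tracts
    replicated: list[GenomicInterval] = []
    for chrom in chroms:
        length = cfg.target_chroms[chrom]
        if cfg.replicated_fraction >= 1.0:
            replicated.append(GenomicInterval(chrom, 0, length))
            continue
        n_reg = int(round(cfg.replicated_fraction * length / cfg.replicated_region_size))
        if n_reg == 0:
            continue
        starts = _place_non_overlapping(
            rng, length, [cfg.replicated_region_size] * n_reg, 0
        )
        replicated.extend(
            GenomicInterval(
                chrom,
                (s // cfg.bin_size) * cfg.bin_size,
                (s // cfg.bin_size) * cfg.bin_size + cfg.replicated_region_size,
            )
            for s in starts
        )

    return Landscape(
        config=cfg,
        target_layout=target,
        spikein_layout=spike,
        peaks=peaks,
        domains=domains,
        replicated=replicated,
        levels=levels,
        categories=categories,
        plateau_hours=plateau,
        loss_folds=folds,
    )


def _segment_table(landscape: Landscape) -> pd.DataFrame:
    """Piecewise-constant density segments per chromosome: features plus the
    background gaps between them. feature_index is -1 for background."""
    cfg = landscape.config
    rows = []
    feats = landscape.features
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {
        c: [] for c in cfg.target_chroms
    }
    for i, f in enumerate(feats):
        by_chrom[f.chrom].append((i, f))
    for chrom, length in cfg.target_chroms.items():
        pos = 0
        for i, f in sorted(by_chrom[chrom], key=lambda t: t[1].start):
            if f.start > pos:
                rows.append((chrom, pos, f.start, -1))
            rows.append((chrom, f.start, f.end, i))
            pos = f.end
        if pos < length:
            rows.append((chrom, pos, length, -1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature"])


def simulate_library(
    landscape: Landscape, replicate: int, timepoint_index: int
) -> Library:
    """Sequence one library (one replicate at one chase timepoint).

    Reads are drawn Poisson from the chromatin composition: target and
    spike-in expected counts split the configured depth in proportion to
    their chromatin mass, so spike-in read share falls as target signal is
    restored — exactly the behavior spike-in normalization corrects for.
    Recycled (parental-derived) fragments are jittered by the displacement
    kernel; restored (new-histone) fragments are not.
    """
    cfg = landscape.config
    label, hours = cfg.timepoints[timepoint_index]
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 1, replicate, timepoint_index])
    )
    segments = _segment_table(landscape)
    level_t = landscape.expected_level(hours)

    seg_feature = segments["feature"].to_numpy()
    seg_len = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    density = np.where(seg_feature >= 0, level_t[seg_feature], cfg.background_level)
    # extra multiplicative noise per feature per library
    if cfg.noise_cv > 0:
        s = np.sqrt(np.log(1 + cfg.noise_cv**2))
        eps = np.exp(rng.normal(-s**2 / 2, s, len(landscape.features)))
        density = density * np.where(seg_feature >= 0, eps[seg_feature], 1.0)
    masses = density * seg_len
    target_mass = masses.sum()

    parental_mass = float(
        np.where(seg_feature >= 0, landscape.levels[seg_feature], cfg.background_level)
        .dot(seg_len)
    )
    spike_mass = cfg.spikein_mass_fraction * parental_mass
    exp_target = cfg.depth * target_mass / (target_mass + spike_mass)
    exp_spike = cfg.depth * spike_mass / (target_mass + spike_mass)

    n_target = rng.poisson(exp_target)
    n_spike = rng.poisson(exp_spike)

    seg_idx = rng.choice(len(masses), size=n_target, p=masses / target_mass)
    offsets = rng.random(n_target) * seg_len[seg_idx]
    pos = segments["start"].to_numpy()[seg_idx] + offsets

    # recycled fraction of each segment's signal at this time
    if cfg.mode == "inhibitor":
        rec_frac_feat = np.ones(len(landscape.features))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            rec_frac_feat = np.where(
                level_t > 0, cfg.dilution * landscape.levels / level_t, 0.0
            )
        rec_frac_feat = np.clip(rec_frac_feat, 0.0, 1.0)
    rec_frac = np.where(seg_feature[seg_idx] >= 0, rec_frac_feat[seg_feature[seg_idx]], 0.0)
    if cfg.displacement_sigma > 0:
        recycled = rng.random(n_target) < rec_frac
        pos[recycled] += rng.normal(0, cfg.displacement_sigma, int(recycled.sum()))

    chrom_of_seg = segments["chrom"].to_numpy()
    read_chroms = chrom_of_seg[seg_idx]
    strands = rng.random(n_target) < 0.5  # True -> "+"

    reads: list[GenomicInterval] = []
    rl = cfg.read_length
    for chrom in cfg.target_chroms:
        mask = read_chroms == chrom
        if not mask.any():
            continue
        clen = cfg.target_chroms[chrom]
        p = np.clip(pos[mask], 0, clen).astype(np.int64)
        plus = strands[mask]
        starts = np.where(plus, np.minimum(p, clen - rl), np.maximum(p - rl, 0))
        ends = starts + rl
        sl = np.where(plus, "+", "-").tolist()
        reads.extend(
            GenomicInterval(chrom, s, e, st)
            for s, e, st in zip(starts.tolist(), ends.tolist(), sl)
        )

    # spike-in reads: uniform over the spike-in genome (constant biology)
    s_chroms = list(cfg.spikein_chroms)
    s_lens = np.array([cfg.spikein_chroms[c] for c in s_chroms], dtype=float)
    s_pick = rng.choice(len(s_chroms), size=n_spike, p=s_lens / s_lens.sum())
    for ci, chrom in enumerate(s_chroms):
        mask = s_pick == ci
        k = int(mask.sum())
        if not k:
            continue
        clen = cfg.spikein_chroms[chrom]
        starts = rng.integers(0, max(clen - rl, 1), size=k)
        plus = rng.random(k) < 0.5
        sl = np.where(plus, "+", "-").tolist()
        reads.extend(
            GenomicInterval(chrom, int(s), int(s) + rl, st)
            for s, st in zip(starts.tolist(), sl)
        )

    return Library(
        replicate=replicate,
        timepoint=label,
        hours=hours,
        reads=reads,
        counts=LibraryCounts(n_target, n_spike),
        expected_target_reads=float(exp_target),
        expected_spikein_reads=float(exp_spike),
    )


@dataclass
class TimeCourseSim:
    """Handle over a full simulated experiment; libraries are produced on
    demand so multi-million-read experiments need not be held in memory."""

    landscape: Landscape

    @property
    def config(self) -> SimulationConfig:
        return self.landscape.config

    @property
    def truth(self) -> pd.DataFrame:
        return self.landscape.truth

    def library(self, replicate: int, timepoint_index: int) -> Library:
        return simulate_library(self.landscape, replicate, timepoint_index)

    def iter_libraries(self) -> Iterator[Library]:
        for rep in range(self.config.replicates):
            for ti in range(len(self.config.timepoints)):
                yield self.library(rep, ti)

    def library_table(self) -> pd.DataFrame:
        rows = []
        for lib in self.iter_libraries():
            rows.append(
                {
                    "replicate": lib.replicate,
                    "timepoint": lib.timepoint,
                    "hours": lib.hours,
                    "target_reads": lib.counts.target_unique_reads,
                    "spikein_reads": lib.counts.spikein_unique_reads,
                    "expected_target_reads": lib.expected_target_reads,
                    "expected_spikein_reads": lib.expected_spikein_reads,
                }
            )
        return pd.DataFrame(rows)


def simulate_timecourse(landscape: Landscape) -> TimeCourseSim:
    """Wrap a landscape as a simulated time-course experiment."""
    return TimeCourseSim(landscape)


def displaced_peaks(
    peaks: Sequence[GenomicInterval],
    sigma: float,
    rng: np.random.Generator,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[GenomicInterval]:
    """Nascent counterparts of parental peaks under coherent recycling: each
    locus keeps its width but shifts by one Gaussian draw (sd ``sigma``),
    emulating re-deposition of the whole recycled nucleosome block near its
    original position. With sigma 0 this is the identity."""
    out = []
    for p in peaks:
        shift = int(round(rng.normal(0, sigma))) if sigma > 0 else 0
        lo = -p.start
        if chrom_lengths is not None:
            shift = min(shift, chrom_lengths[p.chrom] - p.end)
        shift = max(shift, lo)
        out.append(
            GenomicInterval(p.chrom, p.start + shift, p.end + shift, p.strand, name=p.name)
        )
    return out


def naive_domain_caller(
    track: BinnedTrack, threshold: float, min_width: int
) -> list[GenomicInterval]:
    """Fixture-grade caller: maximal runs of bins >= threshold, merged across
    single-bin gaps, kept if at least ``min_width`` bp. Not a peak caller —
    real data goes through MACS upstream of this pipeline."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bs = track.bin_size
    out: list[GenomicInterval] = []
    for chrom, values in track.data.items():
        above = values >= threshold
        # merge runs separated by a gap of one below-threshold bin
        idx = np.flatnonzero(above)
        if idx.size == 0:
            continue
        runs: list[list[int]] = [[idx[0], idx[0]]]
        for i in idx[1:]:
            if i - runs[-1][1] <= 2:  # gap of <= 1 bin
                runs[-1][1] = i
            else:
                runs.append([i, i])
        clen = track.layout.length(chrom)
        for lo, hi in runs:
            start, end = lo * bs, min((hi + 1) * bs, clen)
            if end - start >= min_width:
                out.append(GenomicInterval(chrom, start, end))
    return out
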