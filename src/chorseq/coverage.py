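"""Binned signal tracks and their normalizations.

The measurement model: single-end reads are extended from their 5' alignment
end to the mean library fragment size (250 bp for narrow marks, 500 bp for
broad), then counted into fixed-width non-overlapping bins. Normalizations:

``RPM``
    reads per million target-genome reads — depth-relative, blind to global
    level changes.
``RRPM``
    reference-adjusted RPM: the same counts scaled per million *spike-in*
    reads. Because the exogenous spike-in chromatin is constant across
    samples, RRPM preserves between-sample level differences (the basis of
    the quantitative restoration analysis).
``percent_max`` / ``zscore``
    display scalings applied over whatever region set is being compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genomic_io import GenomeLayout, GenomicInterval, LibraryCounts

__all__ = [
    "BinnedTrack",
    "ZScoreParams",
    "ZeroMaxWarning",
    "extend_reads",
    "bin_counts",
    "rpm",
    "rrpm",
    "rpkm",
    "percent_of_max",
    "zscore",
]

NORMALIZATIONS = ("raw", "RPM", "RRPM", "RPKM", "percent_max", "zscore")


class ZeroMaxWarning(UserWarning):
    """percent-of-max was asked for an all-zero vector; output left at zero."""


@dataclass(slots=True)
class ZScoreParams:
    """Mean and standard deviation used to standardize a signal vector."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class BinnedTrack:
    """Per-chromosome signal over fixed-width non-overlapping bins.

    The trailing bin of each chromosome covers the natural (shorter) remainder
    when the chromosome length is not a bin multiple; ``partial_end_bins``
    records which chromosomes have one.
    """

    bin_size: int
    data: dict[str, np.ndarray]
    layout: GenomeLayout
    normalization: str = "raw"
    mark: Optional[str] = None
    time: Optional[str] = None
    partial_end_bins: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for chrom, values in self.data.items():
            expected = self.layout.n_bins(chrom, self.bin_size)
            if len(values) != expected:
                raise ValueError(
                    f"{chrom}: {len(values)} bins, expected {expected} "
                    f"(length {self.layout.length(chrom)}, bin {self.bin_size})"
                )

    def copy(self) -> "BinnedTrack":
        return replace(self, data={c: v.copy() for c, v in self.data.items()})

    def scaled(self, factor: float, normalization: str) -> "BinnedTrack":
        return replace(
            self,
            data={c: v * factor for c, v in self.data.items()},
            normalization=normalization,
        )

    def values(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def concat(self) -> np.ndarray:
        """All values in layout chromosome order, concatenated."""
        return np.concatenate([self.data[c] for c in self.data]) if self.data else np.array([])

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def window_sum(self, window: GenomicInterval) -> float:
        """Sum of the bins exactly tiling ``window`` (must sit on the bin grid)."""
        bs = self.bin_size
        if window.start % bs or window.end % bs:
            raise ValueError(
                f"window [{window.start},{window.end}) not aligned to {bs} bp bin grid"
            )
        v = self.data[window.chrom]
        return float(v[window.start // bs : window.end // bs].sum())


def extend_reads(
    reads: Sequence[GenomicInterval],
    target_length: int,
    layout: GenomeLayout,
) -> list[GenomicInterval]:
    """Extend each read to ``target_length`` bp from its 5' end in the strand
    direction, clipping to the chromosome. Unstranded reads are treated as
    plus-strand (with a single warning)."""
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    lengths = layout.chrom_sizes
    out: list[GenomicInterval] = []
    warned = False
    for r in reads:
        if r.chrom not in lengths:
            raise ValueError(f"read on chromosome {r.chrom!r} absent from layout")
        clen = lengths[r.chrom]
        strand = r.strand
        if strand == ".":
            if not warned:
                warnings.warn("unstranded read(s) treated as plus-strand for extension")
                warned = True
            strand = "+"
        if strand == "+":
            start, end = r.start, min(r.start + target_length, clen)
        else:
            start, end = max(r.end - target_length, 0), r.end
        out.append(GenomicInterval(r.chrom, start, end, strand))
    return out


def bin_counts(
    extended: Sequence[GenomicInterval],
    bin_size: int,
    layout: GenomeLayout,
) -> BinnedTrack:
    """Count, for every bin, the reads overlapping it by >=1 bp (occupancy-style:
    a read is counted once in every bin it touches)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    per_chrom: dict[str, tuple[list[int], list[int]]] = {c: ([], []) for c in layout}
    for r in extended:
        if r.chrom not in per_chrom:
            raise ValueError(f"read on chromosome {r.chrom!r} absent from layout")
        s, e = per_chrom[r.chrom]
        s.append(r.start)
        e.append(r.end)
    data: dict[str, np.ndarray] = {}
    partial = set()
    for chrom in layout:
        n = layout.n_bins(chrom, bin_size)
        if layout.length(chrom) % bin_size:
            partial.add(chrom)
        starts, ends = per_chrom[chrom]
        diff = np.zeros(n + 1, dtype=np.int64)
        if starts:
            s_arr = np.asarray(starts, dtype=np.int64)
            e_arr = np.asarray(ends, dtype=np.int64)
            first = s_arr // bin_size
            last = (e_arr - 1) // bin_size  # inclusive
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
        data[chrom] = diff.cumsum()[:n].astype(float)
    return BinnedTrack(
        bin_size=bin_size,
        data=data,
        layout=layout,
        normalization="raw",
        partial_end_bins=frozenset(partial),
    )


def rpm(track: BinnedTrack, counts: LibraryCounts) -> BinnedTrack:
    """Scale to reads per million target-genome unique reads."""
    if counts.target_unique_reads <= 0:
        raise ValueError("RPM requires a positive target-genome read total")
    return track.scaled(1e6 / counts.target_unique_reads, "RPM")


def rrpm(track: BinnedTrack, counts: LibraryCounts) -> BinnedTrack:
    """Scale to reference-adjusted RPM: per million spike-in unique reads."""
    if counts.spikein_unique_reads <= 0:
        raise ValueError(
            "RRPM requires spikein_unique_reads > 0: spike-in normalization is "
            "undefined without recovered spike-in reads"
        )
    return track.scaled(1e6 / counts.spikein_unique_reads, "RRPM")


def rpkm(
    region_counts: Sequence[tuple[GenomicInterval, float]],
    counts: LibraryCounts,
) -> np.ndarray:
    """Reads per kilobase per million target reads for arbitrary regions."""
    if counts.target_unique_reads <= 0:
        raise ValueError("RPKM requires a positive target-genome read total")
    out = np.empty(len(region_counts))
    for i, (region, c) in enumerate(region_counts):
        length = region.end - region.start
        if length <= 0:
            raise ValueError(f"zero-length region {region.chrom}:{region.start}")
        out[i] = c * 1e9 / (length * counts.target_unique_reads)
    return out


def percent_of_max(values: np.ndarray) -> np.ndarray:
    """Scale a vector to percent of its maximum (max maps to exactly 100).

    Meant to be applied over the region set actually being displayed/compared
    (one locus, one anchor matrix), not genome-wide. An all-zero input is
    returned unchanged with a :class:`ZeroMaxWarning`.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percent_of_max of an empty vector")
    m = values.max()
    if m == 0:
        warnings.warn("all-zero input to percent_of_max", ZeroMaxWarning)
        return values.copy()
    # divide first so the maximum maps to exactly 100.0 in floating point
    return (values / m) * 100.0


def zscore(values: np.ndarray, ddof: int = 0) -> tuple[np.ndarray, ZScoreParams]:
    """Standardize a vector: z = (x - mu) / sigma.

    sigma is the population (divide-by-n) standard deviation by default;
    ``ddof=1`` gives the sample convention.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("z-score requires at least 2 values")
    mu = float(values.mean())
    sigma = float(values.std(ddof=ddof))
    if sigma == 0:
        raise ValueError("constant signal cannot be z-scored (sigma = 0)")
    return (values - mu) / sigma, ZScoreParams(mu, sigma)
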