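"""Interval algebra for the replication analysis: tiling parental peaks into
fixed-width windows, restricting to replicated DNA, measuring parental ->
nascent peak displacement, and extracting oriented broad-domain borders.

Overlap always means >= 1 bp of intersection under half-open arithmetic
unless a larger ``min_overlap`` is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genomic_io import GenomicInterval

__all__ = [
    "WindowSet",
    "PeakPair",
    "BorderAnchor",
    "DisplacementSummary",
    "tile_peaks",
    "filter_by_overlap",
    "pair_unique_peaks",
    "displacement_summary",
    "domain_borders",
    "merge_intervals",
]


@dataclass
class WindowSet:
    """Non-overlapping fixed-width windows derived from a peak set."""

    window_size: int
    windows: list[GenomicInterval]
    provenance: tuple[Optional[str], Optional[str]] = (None, None)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


@dataclass(slots=True)
class PeakPair:
    """A parental peak matched one-to-one with an overlapping nascent peak."""

    parental: GenomicInterval
    nascent: GenomicInterval
    start_distance: int
    end_distance: int


@dataclass(slots=True)
class BorderAnchor:
    """An oriented edge of a broad domain; ``inside_direction`` says which side
    is domain interior, so profiles can be flipped into a common frame."""

    chrom: str
    position: int
    inside_direction: str  # "left" | "right"

    def __post_init__(self) -> None:
        if self.inside_direction not in ("left", "right"):
            raise ValueError("inside_direction must be 'left' or 'right'")


@dataclass
class DisplacementSummary:
    """Distance statistics over matched parental/nascent peak pairs.

    ``per_pair`` is the mean of the two end distances for each pair;
    ``pooled_ends`` keeps every end distance separately so either aggregation
    convention is recoverable.
    """

    per_pair: np.ndarray
    start_distances: np.ndarray
    end_distances: np.ndarray
    mean: float
    median: float

    @property
    def pooled_ends(self) -> np.ndarray:
        return np.concatenate([self.start_distances, self.end_distances])

    @property
    def pooled_mean(self) -> float:
        return float(self.pooled_ends.mean())


def merge_intervals(regions: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Plain union: overlapping (not merely bookended) intervals are merged."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: list[GenomicInterval] = []
    for chrom in by_chrom:
        ivs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for r in ivs[1:]:
            if r.start < cur_e:
                cur_e = max(cur_e, r.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = r.start, r.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def tile_peaks(
    peaks: Sequence[GenomicInterval],
    window_size: int,
    source_id: Optional[str] = None,
) -> WindowSet:
    """Tile each peak from its start into non-overlapping windows of exactly
    ``window_size`` bp; a trailing remainder shorter than the window is
    dropped so all windows stay size-comparable."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows: list[GenomicInterval] = []
    for p in peaks:
        n = (p.end - p.start) // window_size
        for i in range(n):
            s = p.start + i * window_size
            windows.append(
                GenomicInterval(p.chrom, s, s + window_size, name=p.name)
            )
    return WindowSet(window_size, windows, provenance=(source_id, None))


def _union_tree_by_chrom(regions: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in merge_intervals(regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def filter_by_overlap(
    windows: WindowSet,
    regions: Sequence[GenomicInterval],
    min_overlap: int = 1,
    region_id: Optional[str] = None,
) -> WindowSet:
    """Keep windows whose intersection with the union of ``regions`` is at
    least ``min_overlap`` bp; input order is preserved."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees = _union_tree_by_chrom(regions) if regions else {}
    kept: list[GenomicInterval] = []
    for w in windows:
        tree = trees.get(w.chrom)
        if tree is None:
            continue
        ov = sum(
            min(w.end, hit.end) - max(w.start, hit.begin)
            for hit in tree.overlap(w.start, w.end)
        )
        if ov >= min_overlap:
            kept.append(w)
    return WindowSet(
        windows.window_size,
        kept,
        provenance=(windows.provenance[0], region_id),
    )


def _check_non_overlapping(peaks: Sequence[GenomicInterval], label: str) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda r: (r.start, r.end))
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{label} peaks overlap: {chrom}:[{a.start},{a.end}) and "
                    f"[{b.start},{b.end})"
                )


def pair_unique_peaks(
    parental: Sequence[GenomicInterval],
    nascent: Sequence[GenomicInterval],
) -> list[PeakPair]:
    """Match peaks that overlap each other exactly once in both directions and
    record the absolute start/end coordinate distances of each match.

    Each input list must itself be non-overlapping. The operation is
    symmetric: swapping the inputs swaps pair roles but preserves distances.
    """
    _check_non_overlapping(parental, "parental")
    _check_non_overlapping(nascent, "nascent")
    n_trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(nascent):
        n_trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)
    nascent_hits = np.zeros(len(nascent), dtype=int)
    candidate: list[tuple[GenomicInterval, int]] = []
    for p in parental:
        tree = n_trees.get(p.chrom)
        hits = sorted(tree.overlap(p.start, p.end), key=lambda h: h.begin) if tree else []
        for h in hits:
            nascent_hits[h.data] += 1
        if len(hits) == 1:
            candidate.append((p, hits[0].data))
    pairs: list[PeakPair] = []
    for p, ni in candidate:
        if nascent_hits[ni] != 1:
            continue  # that nascent peak also touched another parental peak
        n = nascent[ni]
        pairs.append(
            PeakPair(
                parental=p,
                nascent=n,
                start_distance=abs(p.start - n.start),
                end_distance=abs(p.end - n.end),
            )
        )
    return pairs


def displacement_summary(pairs: Sequence[PeakPair]) -> DisplacementSummary:
    """Per-pair displacement = mean of the two end distances; the summary also
    carries the raw per-end vectors (pooled convention recoverable)."""
    if not pairs:
        raise ValueError("no peak pairs to summarize")
    sd = np.array([p.start_distance for p in pairs], dtype=float)
    ed = np.array([p.end_distance for p in pairs], dtype=float)
    per_pair = (sd + ed) / 2.0
    return DisplacementSummary(
        per_pair=per_pair,
        start_distances=sd,
        end_distances=ed,
        mean=float(per_pair.mean()),
        median=float(np.median(per_pair)),
    )


def domain_borders(
    domains: Sequence[GenomicInterval],
    replicated: Sequence[GenomicInterval],
    min_distance: int = 5000,
) -> list[BorderAnchor]:
    """Both edges of each broad domain as oriented anchors, excluding any
    anchor within ``min_distance`` bp of a replicated-region edge (domain
    borders that coincide with replication-tract borders would contaminate a
    border-averaged profile)."""
    _check_non_overlapping(domains, "domain")
    if not replicated:
        raise ValueError(
            "no replicated regions given; border anchors require replicated "
            "tracts to measure edge distances against"
        )
    edge_lists: dict[str, list[int]] = {}
    for r in merge_intervals(replicated):
        edge_lists.setdefault(r.chrom, []).extend((r.start, r.end))
    edges = {c: np.asarray(v) for c, v in edge_lists.items()}
    anchors: list[BorderAnchor] = []
    for d in domains:
        for position, inside in ((d.start, "right"), (d.end, "left")):
            chrom_edges = edges.get(d.chrom)
            if chrom_edges is None:
                continue
            if np.abs(chrom_edges - position).min() < min_distance:
                continue
            anchors.append(BorderAnchor(d.chrom, position, inside))
    return anchors
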