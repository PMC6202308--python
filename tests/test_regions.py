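"""Window tiling, replicated-DNA filtering, unique peak pairing and domain
borders — each against brute-force oracles on random instances."""

import numpy as np
import pytest

from conftest import random_intervals
from chorseq.genomic_io import GenomicInterval
from chorseq.regions import (
    WindowSet,
    displacement_summary,
    domain_borders,
    filter_by_overlap,
    merge_intervals,
    pair_unique_peaks,
    tile_peaks,
)


def brute_force_overlap_bp(window, regions):
    """Oracle: per-base membership count of the region union inside window."""
    covered = set()
    for r in regions:
        if r.chrom == window.chrom:
            covered.update(range(max(r.start, window.start), min(r.end, window.end)))
    return len(covered)


class TestTilePeaks:
    def test_exact_tiling(self):
        ws = tile_peaks([GenomicInterval("chr1", 0, 100)], 25)
        assert [(w.start, w.end) for w in ws] == [(0, 25), (25, 50), (50, 75), (75, 100)]

    def test_remainder_dropped(self):
        ws = tile_peaks([GenomicInterval("chr1", 0, 110)], 25)
        assert len(ws) == 4 and ws.windows[-1].end == 100

    def test_short_peak_yields_nothing(self):
        assert len(tile_peaks([GenomicInterval("chr1", 0, 20)], 25)) == 0

    def test_total_length_invariant(self, rng):
        peaks = random_intervals(rng, 200)
        ws = tile_peaks(peaks, 30)
        expected = sum(((p.end - p.start) // 30) * 30 for p in peaks)
        assert sum(w.end - w.start for w in ws) == expected


class TestFilterByOverlap:
    def test_one_bp_overlap_kept_boundary_dropped(self):
        ws = WindowSet(25, [GenomicInterval("chr1", 0, 25)])
        assert len(filter_by_overlap(ws, [GenomicInterval("chr1", 20, 30)])) == 1
        assert len(filter_by_overlap(ws, [GenomicInterval("chr1", 25, 50)])) == 0

    def test_min_overlap_threshold(self):
        ws = WindowSet(25, [GenomicInterval("chr1", 0, 25)])
        region = [GenomicInterval("chr1", 20, 30)]  # 5 bp overlap
        assert len(filter_by_overlap(ws, region, min_overlap=5)) == 1
        assert len(filter_by_overlap(ws, region, min_overlap=6)) == 0

    def test_matches_brute_force_on_random_instances(self, rng):
        windows = WindowSet(0, random_intervals(rng, 500))
        regions = random_intervals(rng, 120)
        kept = filter_by_overlap(windows, regions, min_overlap=10)
        oracle = [
            w for w in windows if brute_force_overlap_bp(w, regions) >= 10
        ]
        assert [(w.start, w.end) for w in kept] == [(w.start, w.end) for w in oracle]


def brute_force_unique_pairs(parental, nascent):
    """Oracle: quadratic overlap counting in both directions."""
    pairs = []
    for p in parental:
        hits = [n for n in nascent if p.overlaps(n)]
        if len(hits) == 1:
            n = hits[0]
            if sum(1 for q in parental if q.overlaps(n)) == 1:
                pairs.append((p, n))
    return pairs


class TestPairUniquePeaks:
    def test_simple_pair_distances(self):
        pairs = pair_unique_peaks(
            [GenomicInterval("chr1", 100, 300)], [GenomicInterval("chr1", 150, 350)]
        )
        assert pairs[0].start_distance == 50 and pairs[0].end_distance == 50

    def test_double_overlap_excluded(self):
        parental = [GenomicInterval("chr1", 0, 500)]
        nascent = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        assert pair_unique_peaks(parental, nascent) == []

    def test_identical_lists_give_zero_distances(self, rng):
        peaks = sorted(random_intervals(rng, 30), key=lambda p: p.start)
        peaks = [p for i, p in enumerate(peaks) if i == 0 or p.start >= peaks[i - 1].end]
        pairs = pair_unique_peaks(peaks, peaks)
        assert len(pairs) == len(peaks)
        assert displacement_summary(pairs).mean == 0.0

    def test_overlapping_input_list_rejected(self):
        bad = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)]
        with pytest.raises(ValueError, match="overlap"):
            pair_unique_peaks(bad, [GenomicInterval("chr1", 0, 10)])

    def _non_overlapping(self, rng, n, chrom_len=50_000):
        ivs = sorted(random_intervals(rng, n, chrom_len=chrom_len, max_len=300),
                     key=lambda p: p.start)
        out = []
        for p in ivs:
            if not out or p.start >= out[-1].end:
                out.append(p)
        return out

    def test_matches_brute_force_and_symmetry(self, rng):
        parental = self._non_overlapping(rng, 150)
        nascent = self._non_overlapping(rng, 150)
        pairs = pair_unique_peaks(parental, nascent)
        oracle = brute_force_unique_pairs(parental, nascent)
        assert [(p.parental.start, p.nascent.start) for p in pairs] == [
            (p.start, n.start) for p, n in oracle
        ]
        swapped = pair_unique_peaks(nascent, parental)
        assert sorted((p.start_distance, p.end_distance) for p in pairs) == sorted(
            (p.start_distance, p.end_distance) for p in swapped
        )


class TestDisplacementSummary:
    def test_per_pair_mean_of_both_ends(self):
        peaks = [
            (GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)),
            (GenomicInterval("chr1", 1000, 1100), GenomicInterval("chr1", 1000, 1200)),
        ]
        pairs = []
        for p, n in peaks:
            pairs.extend(pair_unique_peaks([p], [n]))
        s = displacement_summary(pairs)
        assert s.per_pair.tolist() == [50.0, 50.0]
        assert s.mean == 50.0
        assert s.pooled_ends.tolist() == [50.0, 0.0, 50.0, 100.0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no peak pairs"):
            displacement_summary([])


class TestDomainBorders:
    def test_both_edges_oriented(self):
        anchors = domain_borders(
            [GenomicInterval("chr1", 10_000, 30_000)],
            [GenomicInterval("chr1", 0, 100_000)],
        )
        assert [(a.position, a.inside_direction) for a in anchors] == [
            (10_000, "right"),
            (30_000, "left"),
        ]

    def test_anchor_near_replicated_edge_dropped(self):
        anchors = domain_borders(
            [GenomicInterval("chr1", 3_000, 30_000)],
            [GenomicInterval("chr1", 0, 100_000)],
        )
        # start edge is 3 kb from the replicated edge at 0 -> dropped
        assert [(a.position, a.inside_direction) for a in anchors] == [(30_000, "left")]

    def test_empty_replicated_set_rejected(self):
        with pytest.raises(ValueError, match="replicated"):
            domain_borders([GenomicInterval("chr1", 0, 10)], [])


def test_merge_intervals_union(rng):
    ivs = random_intervals(rng, 100)
    merged = merge_intervals(ivs)
    covered = set()
    for r in ivs:
        covered.update(range(r.start, r.end))
    assert sum(m.end - m.start for m in merged) == len(covered)
    assert all(a.end <= b.start for a, b in zip(merged, merged[1:]))
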