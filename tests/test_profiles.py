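"""Anchored profiles, metagene resampling, heatmap scaling and the Hilbert
mapping (bijectivity/adjacency exhaustively, locality by spot check)."""

import numpy as np
import pytest

from chorseq.coverage import BinnedTrack, ZeroMaxWarning
from chorseq.genomic_io import GenomeLayout, GenomicInterval
from chorseq.profiles import (
    anchor_profile,
    anchored_body_profile,
    heatmap_matrix,
    hilbert_index_to_xy,
    hilbert_map,
)
from chorseq.regions import BorderAnchor


@pytest.fixture
def track(layout):
    vals = {c: np.zeros(layout.n_bins(c, 25)) for c in layout}
    return BinnedTrack(25, vals, layout)


class TestAnchorProfile:
    def test_constant_track_constant_profile(self, layout):
        tr = BinnedTrack(25, {"chr1": np.full(400, 3.0)}, layout)
        mat = anchor_profile(tr, [BorderAnchor("chr1", 5000, "right")], flank=500)
        assert mat.matrix.shape == (1, 40)
        assert (mat.column_means == 3.0).all()

    def test_orientation_flips_step(self, layout):
        vals = np.zeros(400)
        vals[200:] = 6.0  # step up at position 5000
        tr = BinnedTrack(25, {"chr1": vals}, layout)
        plus = anchor_profile(tr, [BorderAnchor("chr1", 5000, "right")], 500)
        minus = anchor_profile(tr, [BorderAnchor("chr1", 5000, "left")], 500)
        assert plus.matrix[0].tolist() == [0.0] * 20 + [6.0] * 20
        assert minus.matrix[0].tolist() == [6.0] * 20 + [0.0] * 20

    def test_out_of_bounds_anchor_dropped_not_clipped(self, layout):
        tr = BinnedTrack(25, {"chr1": np.zeros(400)}, layout)
        mat = anchor_profile(
            tr,
            [BorderAnchor("chr1", 100, "right"), BorderAnchor("chr1", 5000, "right")],
            500,
        )
        assert mat.matrix.shape == (1, 40) and mat.n_dropped == 1

    def test_matches_brute_force_extraction(self, layout, rng):
        vals = rng.random(400)
        tr = BinnedTrack(25, {"chr1": vals}, layout)
        anchors = [
            GenomicInterval("chr1", int(p), int(p) + 50, str(s))
            for p, s in zip(rng.integers(1000, 9000, 100), rng.choice(["+", "-"], 100))
        ]
        mat = anchor_profile(tr, anchors, 500)
        rows = []
        for a in anchors:
            c = round(((a.start + a.end) // 2) / 25)
            row = vals[c - 20 : c + 20]
            rows.append(row[::-1] if a.strand == "-" else row)
        np.testing.assert_allclose(mat.matrix, np.array(rows))


class TestAnchoredBodyProfile:
    def test_constant_body(self, layout):
        tr = BinnedTrack(25, {"chr1": np.full(400, 2.0)}, layout)
        mat = anchored_body_profile(
            tr, [GenomicInterval("chr1", 1000, 2000, "+")], body_bins=10, flank=0
        )
        np.testing.assert_allclose(mat.matrix[0], np.full(10, 2.0))

    def test_length_invariance_of_identical_shapes(self, layout):
        # linear ramp over different lengths resamples to the same row
        vals = np.zeros(400)
        vals[40:80] = np.linspace(0, 1, 40)  # 1 kb body at 1000
        vals[160:240] = np.linspace(0, 1, 80)  # 2 kb body at 4000
        tr = BinnedTrack(25, {"chr1": vals}, layout)
        mat = anchored_body_profile(
            tr,
            [GenomicInterval("chr1", 1000, 2000, "+"), GenomicInterval("chr1", 4000, 6000, "+")],
            body_bins=20,
            flank=0,
        )
        np.testing.assert_allclose(mat.matrix[0], mat.matrix[1], atol=0.02)

    def test_minus_strand_reversed(self, layout):
        vals = np.zeros(400)
        vals[40:80] = np.arange(40, dtype=float)
        tr = BinnedTrack(25, {"chr1": vals}, layout)
        plus = anchored_body_profile(tr, [GenomicInterval("chr1", 1000, 2000, "+")], 40, 0)
        minus = anchored_body_profile(tr, [GenomicInterval("chr1", 1000, 2000, "-")], 40, 0)
        np.testing.assert_allclose(minus.matrix[0], plus.matrix[0][::-1])

    def test_mean_signal_conserved(self, layout, rng):
        vals = rng.random(400)
        tr = BinnedTrack(25, {"chr1": vals}, layout)
        body = GenomicInterval("chr1", 1000, 3000, "+")
        mat = anchored_body_profile(tr, [body], body_bins=16, flank=0)
        assert abs(mat.matrix[0].mean() - vals[40:120].mean()) < 1e-6

    def test_too_short_body_dropped(self, layout):
        tr = BinnedTrack(25, {"chr1": np.zeros(400)}, layout)
        with pytest.raises(ValueError, match="no bodies"):
            anchored_body_profile(tr, [GenomicInterval("chr1", 0, 50, "+")], body_bins=100)


class TestHeatmapMatrix:
    def test_max_cell_becomes_100_and_idempotent(self):
        m = np.array([[1.0, 8.0], [2.0, 4.0]])
        out = heatmap_matrix(m)
        assert out.max() == 100.0 and out[0, 0] == 12.5
        np.testing.assert_allclose(heatmap_matrix(out), out)

    def test_zero_matrix_flagged(self):
        with pytest.warns(ZeroMaxWarning):
            out = heatmap_matrix(np.zeros((2, 2)))
        assert (out == 0).all()


class TestHilbert:
    def test_order1_visit_order(self):
        img = hilbert_map(np.array([1.0, 2.0, 3.0, 4.0]), 1)
        # (x,y) visit order (0,0),(0,1),(1,1),(1,0); grid is [y, x]
        assert img.grid[0, 0] == 1 and img.grid[1, 0] == 2
        assert img.grid[1, 1] == 3 and img.grid[0, 1] == 4

    @pytest.mark.parametrize("order", range(1, 7))
    def test_bijective_and_adjacent_exhaustively(self, order):
        cells = [hilbert_index_to_xy(d, order) for d in range(4**order)]
        assert len(set(cells)) == 4**order
        side = 2**order
        assert all(0 <= x < side and 0 <= y < side for x, y in cells)
        assert all(
            abs(x1 - x2) + abs(y1 - y2) == 1
            for (x1, y1), (x2, y2) in zip(cells, cells[1:])
        )

    def test_locality_monotone_spot_check(self):
        order = 5
        cells = np.array([hilbert_index_to_xy(d, order) for d in range(4**order)])
        rng = np.random.default_rng(0)

        def mean_grid_distance(d):
            idx = rng.integers(0, 4**order - d, 500)
            return np.abs(cells[idx] - cells[idx + d]).sum(axis=1).mean()

        assert mean_grid_distance(1) <= mean_grid_distance(4 ** (order - 1))

    def test_pooling_and_padding(self):
        img = hilbert_map(np.ones(10), 2)  # 16 cells, 6 padded
        assert img.n_padded == 6
        img2 = hilbert_map(np.arange(64, dtype=float), 2)  # mean-pool 4:1
        assert img2.n_padded == 0
        assert img2.grid[0, 0] == np.arange(4).mean()

    def test_constant_input_constant_image(self):
        img = hilbert_map(np.full(64, 5.0), 3)  # order 3 -> exactly 64 cells
        assert (img.grid == 5.0).all()

    def test_order_zero_rejected(self):
        with pytest.raises(ValueError, match="order"):
            hilbert_map(np.ones(4), 0)
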