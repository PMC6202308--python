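"""Time-course assembly and the restoration / loss classifiers, including an
exhaustive boundary grid against an independent reclassification oracle."""

import numpy as np
import pytest

from chorseq.coverage import BinnedTrack
from chorseq.genomic_io import GenomeLayout, GenomicInterval
from chorseq.regions import WindowSet
from chorseq.restoration import (
    TimeCourse,
    assemble_timecourse,
    category_proportions,
    classify_loss,
    classify_restoration,
    replicate_concordance,
)

TP4 = [("T0", 0.0), ("T1", 1.0), ("T6", 6.0), ("T12", 12.0)]


def make_tc(levels, timepoints=None, window_size=500):
    """TimeCourse from a list of per-window level vectors."""
    timepoints = timepoints or TP4
    levels = np.asarray(levels, dtype=float)
    windows = WindowSet(
        window_size,
        [
            GenomicInterval("chr1", i * window_size, (i + 1) * window_size, name=f"w{i}")
            for i in range(len(levels))
        ],
    )
    return TimeCourse("mark", "rep1", timepoints, windows, levels)


class TestAssembleTimecourse:
    def test_window_sums_bins(self, layout):
        tracks = [
            (lab, hr, BinnedTrack(25, {"chr1": np.full(400, v)}, layout))
            for (lab, hr), v in zip(TP4, [1.0, 2.0, 3.0, 4.0])
        ]
        ws = WindowSet(500, [GenomicInterval("chr1", 0, 500)])
        tc = assemble_timecourse(tracks, ws)
        # 20 bins of 25 bp per 500 bp window
        assert tc.matrix.tolist() == [[20.0, 40.0, 60.0, 80.0]]

    def test_off_grid_window_rejected(self, layout):
        tracks = [(lab, hr, BinnedTrack(25, {"chr1": np.zeros(400)}, layout)) for lab, hr in TP4]
        ws = WindowSet(500, [GenomicInterval("chr1", 10, 510)])
        with pytest.raises(ValueError, match="not aligned"):
            assemble_timecourse(tracks, ws)

    def test_hand_summed_fixture(self, layout):
        vals = np.arange(400, dtype=float)
        tracks = [(lab, hr, BinnedTrack(25, {"chr1": vals * (j + 1)}, layout))
                  for j, (lab, hr) in enumerate(TP4[:2])]
        ws = WindowSet(100, [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)])
        tc = assemble_timecourse(tracks, ws, )
        assert tc.matrix[0, 0] == sum(range(4))
        assert tc.matrix[1, 1] == 2 * sum(range(8, 12))


def oracle_restoration_category(levels, labels, threshold):
    """Independent restatement of the rule: earliest timepoint whose level is
    within `threshold`-fold of the final level."""
    final = levels[-1]
    for lab, lev in zip(labels[:-1], levels[:-1]):
        ratio = float("inf") if lev == 0 else final / lev
        if ratio <= threshold:
            return lab
    return labels[-1]


class TestClassifyRestoration:
    @pytest.mark.parametrize(
        "levels,expected",
        [
            ([1, 2, 4, 4], "T6"),
            ([4, 4, 4, 4], "T0"),
            ([1, 3, 3, 3], "T1"),
            ([1, 1, 1, 4], "T12"),
            ([0, 2, 4, 4], "T6"),  # zero level -> infinite ratio at T0
            ([8, 2, 4, 4], "T0"),  # non-monotone trace: T0 already above final
        ],
    )
    def test_stated_rule_examples(self, levels, expected):
        (call,) = classify_restoration(make_tc([levels])).calls
        assert call.category == expected

    def test_boundary_grid_matches_oracle_exactly(self):
        # all 4-level combinations around the 1.5 threshold boundaries
        grid = [0.0, 1.0, 1.5, 2.24, 2.25, 2.26, 3.0, 3.375]
        vectors = [
            (a, b, c, 3.375)
            for a in grid
            for b in grid
            for c in grid
        ]
        tc = make_tc(vectors)
        calls = classify_restoration(tc).calls
        labels = [lab for lab, _ in TP4]
        assert len(calls) == len(vectors)
        for call, lev in zip(calls, vectors):
            assert call.category == oracle_restoration_category(lev, labels, 1.5), lev

    def test_zero_final_reported_not_dropped_silently(self):
        res = classify_restoration(make_tc([[1, 1, 1, 0], [1, 1, 1, 2]]))
        assert len(res.calls) == 1 and res.n_unclassifiable == 1

    def test_scale_invariance(self, rng):
        levels = rng.random((50, 4)) * 10 + 0.1
        base = [c.category for c in classify_restoration(make_tc(levels)).calls]
        scaled = [c.category for c in classify_restoration(make_tc(levels * 37.0)).calls]
        assert base == scaled

    def test_monotone_in_earlier_levels(self, rng):
        labels = [lab for lab, _ in TP4]
        for _ in range(200):
            lev = rng.random(4) * 4 + 0.05
            (c1,) = classify_restoration(make_tc([lev])).calls
            j = rng.integers(0, 3)
            lev2 = lev.copy()
            lev2[j] *= 1 + rng.random()
            (c2,) = classify_restoration(make_tc([lev2])).calls
            assert labels.index(c2.category) <= labels.index(c1.category)

    def test_strict_mode_drops_windows_never_exceeding_threshold(self):
        res = classify_restoration(make_tc([[4, 4, 4, 4], [1, 2, 4, 4]]), strict=True)
        assert len(res.calls) == 1 and len(res.strict_dropped) == 1
        assert res.calls[0].category == "T6"


class TestReplicateConcordance:
    def test_keeps_matching_drops_mismatching(self):
        tc1 = make_tc([[1, 2, 4, 4], [4, 4, 4, 4]])
        tc2 = make_tc([[1, 2, 4, 4], [1, 3, 3, 3]])
        r1 = classify_restoration(tc1).calls
        r2 = classify_restoration(tc2).calls
        conc = replicate_concordance(r1, r2)
        assert len(conc.calls) == 1 and conc.calls[0].category == "T6"
        assert conc.calls[0].concordant is True
        assert conc.retained_fraction == 0.5

    def test_identical_replicates_fully_retained(self):
        calls = classify_restoration(make_tc([[1, 2, 4, 4]] * 5)).calls
        assert replicate_concordance(calls, calls).retained_fraction == 1.0

    def test_window_mismatch_rejected(self):
        c1 = classify_restoration(make_tc([[1, 2, 4, 4]])).calls
        c2 = classify_restoration(make_tc([[1, 2, 4, 4]], window_size=250)).calls
        with pytest.raises(ValueError, match="window sets differ"):
            replicate_concordance(c1, c2)


def oracle_loss_category(t0, t24, low=1.5, high=3.0):
    if t24 == 0:
        return None if t0 == 0 else "high"
    fold = t0 / t24
    if fold < low:
        return "low"
    if fold <= high:
        return "moderate"
    return "high"


class TestClassifyLoss:
    TP2 = [("T0", 0.0), ("T24", 24.0)]

    @pytest.mark.parametrize(
        "t0,t24,expected",
        [(10, 9, "low"), (10, 5, "moderate"), (10, 2, "high"),
         (15, 10, "moderate"), (3, 2, "moderate"), (30, 10, "moderate"), (30.1, 10, "high")],
    )
    def test_stated_boundaries(self, t0, t24, expected):
        (call,) = classify_loss(make_tc([[t0, t24]], self.TP2)).calls
        assert call.category == expected

    def test_zero_final_is_total_loss_flagged(self):
        (call,) = classify_loss(make_tc([[10, 0]], self.TP2)).calls
        assert call.category == "high" and call.zero_final

    def test_double_zero_unclassifiable(self):
        res = classify_loss(make_tc([[0, 0]], self.TP2))
        assert res.calls == [] and res.n_unclassifiable == 1

    def test_random_grid_matches_oracle(self, rng):
        vals = np.round(rng.random((300, 2)) * 6, 2)
        res = classify_loss(make_tc(vals, self.TP2))
        got = iter(res.calls)
        for t0, t24 in vals:
            want = oracle_loss_category(t0, t24)
            if want is None:
                continue
            assert next(got).category == want, (t0, t24)

    def test_needs_exactly_two_timepoints(self):
        with pytest.raises(ValueError, match="exactly 2"):
            classify_loss(make_tc([[1, 2, 3, 4]]))


class TestCategoryProportions:
    def test_even_split(self):
        calls = classify_restoration(make_tc([[1, 3, 3, 3]] * 50 + [[1, 1, 1.5, 3]] * 50)).calls
        props = category_proportions(calls)
        assert props == {"T1": 0.5, "T12": 0.5}

    def test_partition_sums_to_one(self, rng):
        calls = classify_restoration(make_tc(rng.random((200, 4)) + 0.01)).calls
        props = category_proportions(calls, order=[lab for lab, _ in TP4])
        assert abs(sum(props.values()) - 1) < 1e-12
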