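"""Restoration-kinetics classification of spike-in-normalized time courses.

Each genomic window carries an RRPM level at every timepoint of a chase
experiment (e.g. T0/T1/T6/T12 after replication). Its restoration category is
the earliest timepoint at which the window has already reached its
final-timepoint level, judged by the ratio

    final_level / level(t)  <=  fold_threshold        (default 1.5)

so "R0" means restored immediately (pure parental-histone recycling suffices),
"R6" means the final level is reached only 6 h after replication, etc. Windows
are called per replicate and only windows with the same category in both
replicates are kept (replicate concordance).

Under methyltransferase inhibition there is no restoration and the complement
is measured instead: the T0/T24 fold *loss* of recycled signal, binned into
low (< 1.5), moderate (1.5 - 3) and high (> 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .coverage import BinnedTrack
from .genomic_io import GenomicInterval, LibraryCounts
from .regions import WindowSet

__all__ = [
    "TimeCourse",
    "RestorationCall",
    "LossCall",
    "ClassificationResult",
    "ConcordanceResult",
    "assemble_timecourse",
    "classify_restoration",
    "replicate_concordance",
    "classify_loss",
    "category_proportions",
]


@dataclass
class TimeCourse:
    """Windows x timepoints matrix of (normally RRPM) signal for one mark and
    replicate, plus the per-timepoint library totals that produced it."""

    mark: str
    replicate: str
    timepoints: list[tuple[str, float]]  # (label, hours), strictly increasing
    windows: WindowSet
    matrix: np.ndarray
    library_counts: Optional[list[LibraryCounts]] = None

    def __post_init__(self) -> None:
        hours = [h for _, h in self.timepoints]
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("timepoints must be strictly increasing in hours")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.windows), len(self.timepoints)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != "
                f"({len(self.windows)} windows, {len(self.timepoints)} timepoints)"
            )
        if (self.matrix < 0).any():
            raise ValueError("negative signal in time course matrix")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.timepoints]


@dataclass(slots=True)
class RestorationCall:
    window: GenomicInterval
    ratios: np.ndarray  # final/level(t) for each non-final timepoint
    category: str  # one of the timepoint labels
    concordant: Optional[bool] = None


@dataclass(slots=True)
class LossCall:
    window: GenomicInterval
    fold_change: float  # T0 / T24
    category: str  # low | moderate | high
    concordant: Optional[bool] = None
    zero_final: bool = False


@dataclass
class ClassificationResult:
    """Calls plus the windows that could not be classified (zero reference
    signal), which are counted and reported, never silently dropped."""

    calls: list
    unclassifiable: list[GenomicInterval] = field(default_factory=list)
    strict_dropped: list[GenomicInterval] = field(default_factory=list)

    @property
    def n_unclassifiable(self) -> int:
        return len(self.unclassifiable)


@dataclass
class ConcordanceResult:
    calls: list
    retained_fraction: float
    n_input: int


def assemble_timecourse(
    tracks: Sequence[tuple[str, float, BinnedTrack]],
    windows: WindowSet,
    mark: str = "",
    replicate: str = "rep1",
    library_counts: Optional[Sequence[LibraryCounts]] = None,
) -> TimeCourse:
    """Sum each window's constituent bins at every timepoint.

    ``tracks`` is a list of (label, hours, BinnedTrack); all tracks must share
    bin size and layout, windows must sit on the bin grid, and the matrix is
    complete by construction (a window missing from a track's layout is an
    error, not a missing cell).
    """
    if not tracks:
        raise ValueError("no tracks given")
    bin_size = tracks[0][2].bin_size
    for label, _, tr in tracks:
        if tr.bin_size != bin_size:
            raise ValueError(f"track {label!r} has bin size {tr.bin_size} != {bin_size}")
    if windows.window_size % bin_size:
        raise ValueError(
            f"window size {windows.window_size} is not a multiple of bin size {bin_size}"
        )
    matrix = np.empty((len(windows), len(tracks)))
    for j, (_, _, tr) in enumerate(tracks):
        for i, w in enumerate(windows):
            matrix[i, j] = tr.window_sum(w)
    return TimeCourse(
        mark=mark,
        replicate=replicate,
        timepoints=[(lab, hr) for lab, hr, _ in tracks],
        windows=windows,
        matrix=matrix,
        library_counts=list(library_counts) if library_counts is not None else None,
    )


def classify_restoration(
    tc: TimeCourse,
    fold_threshold: float = 1.5,
    inclusive: bool = True,
    strict: bool = False,
) -> ClassificationResult:
    """Assign each window the earliest timepoint at which it reached its
    final level.

    A window's category is the first timepoint ``t`` with
    ``final / level(t) <= fold_threshold`` (``<`` if ``inclusive=False``); the
    final timepoint trivially satisfies this, so every window with non-zero
    final signal gets a category. ``level(t) = 0`` yields an infinite ratio at
    that timepoint. Windows with zero final signal are unclassifiable and
    reported separately.

    ``strict=True`` additionally drops windows none of whose pre-final ratios
    exceed the threshold (the literal "only bins with ratios > threshold were
    considered" reading, which removes already-restored R0 windows a priori).
    """
    if len(tc.timepoints) < 2:
        raise ValueError("restoration classification needs >= 2 timepoints")
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    labels = tc.labels
    final = tc.matrix[:, -1]
    result = ClassificationResult(calls=[])
    for i, w in enumerate(tc.windows):
        if final[i] == 0:
            result.unclassifiable.append(w)
            continue
        earlier = tc.matrix[i, :-1]
        with np.errstate(divide="ignore"):
            ratios = np.where(earlier > 0, final[i] / np.where(earlier > 0, earlier, 1), np.inf)
        if strict and not (ratios > fold_threshold).any():
            result.strict_dropped.append(w)
            continue
        reached = ratios <= fold_threshold if inclusive else ratios < fold_threshold
        idx = int(np.argmax(reached)) if reached.any() else len(labels) - 1
        result.calls.append(
            RestorationCall(window=w, ratios=ratios, category=labels[idx])
        )
    return result


def replicate_concordance(
    calls_rep1: Sequence[Union[RestorationCall, LossCall]],
    calls_rep2: Sequence[Union[RestorationCall, LossCall]],
) -> ConcordanceResult:
    """Keep windows whose category is identical in both replicates.

    The two call lists must cover the same windows in the same order.
    Retained calls carry rep1's values with ``concordant=True``.
    """
    if len(calls_rep1) != len(calls_rep2):
        raise ValueError(
            f"replicate call lists differ in length: {len(calls_rep1)} vs {len(calls_rep2)}"
        )
    kept = []
    for c1, c2 in zip(calls_rep1, calls_rep2):
        w1, w2 = c1.window, c2.window
        if (w1.chrom, w1.start, w1.end) != (w2.chrom, w2.start, w2.end):
            raise ValueError(
                f"replicate window sets differ: {w1.chrom}:{w1.start} vs {w2.chrom}:{w2.start}"
            )
        if c1.category == c2.category:
            kept.append(replace_concordant(c1))
    frac = len(kept) / len(calls_rep1) if calls_rep1 else 0.0
    return ConcordanceResult(calls=kept, retained_fraction=frac, n_input=len(calls_rep1))


def replace_concordant(call):
    if isinstance(call, RestorationCall):
        return RestorationCall(call.window, call.ratios, call.category, True)
    return LossCall(call.window, call.fold_change, call.category, True, call.zero_final)


def classify_loss(
    tc: TimeCourse,
    low_cut: float = 1.5,
    high_cut: float = 3.0,
    inclusive_band: bool = True,
) -> ClassificationResult:
    """Bin each window's T0/T-final fold loss into low/moderate/high.

    Requires exactly two timepoints (nascent and the late chase, e.g. T0 and
    T24). With the default closed band: low if fold < low_cut, moderate if
    low_cut <= fold <= high_cut, high if fold > high_cut. A zero final level
    with non-zero T0 is total loss -> high, flagged; zero at both timepoints
    is unclassifiable.
    """
    if len(tc.timepoints) != 2:
        raise ValueError("loss classification needs exactly 2 timepoints (T0 and final)")
    if not 0 < low_cut <= high_cut:
        raise ValueError("need 0 < low_cut <= high_cut")
    result = ClassificationResult(calls=[])
    for i, w in enumerate(tc.windows):
        t0, tf = tc.matrix[i]
        if tf == 0:
            if t0 == 0:
                result.unclassifiable.append(w)
                continue
            result.calls.append(LossCall(w, math.inf, "high", zero_final=True))
            continue
        fold = t0 / tf
        if inclusive_band:
            cat = "low" if fold < low_cut else ("moderate" if fold <= high_cut else "high")
        else:
            cat = "low" if fold <= low_cut else ("moderate" if fold < high_cut else "high")
        result.calls.append(LossCall(w, fold, cat))
    return result


def category_proportions(
    calls: Sequence[Union[RestorationCall, LossCall]],
    order: Optional[Sequence[str]] = None,
) -> dict[str, float]:
    """Fraction of classified windows per category; proportions sum to 1."""
    if not calls:
        raise ValueError("no calls to summarize")
    counts: dict[str, int] = {}
    if order is not None:
        for lab in order:
            counts[lab] = 0
    for c in calls:
        counts[c.category] = counts.get(c.category, 0) + 1
    n = len(calls)
    return {lab: counts[lab] / n for lab in counts}
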