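"""Genomic interval types and strict readers/writers for the text formats
the pipeline touches (BED3-6, ENCODE narrowPeak/broadPeak, bedGraph,
chrom-sizes).

All coordinates are 0-based half-open ``[start, end)`` internally, the BED
convention. Spike-in reads are distinguished from target reads purely by
chromosome-name membership in the spike-in :class:`GenomeLayout`, mirroring
dual-genome (human + Drosophila) alignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "LibraryCounts",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_peaks",
    "write_broadpeak",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "split_by_genome",
    "count_library",
    "filter_peaks_by_qvalue",
]

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Malformed record in a BED-family file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(slots=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Constructor does not validate (interval lists routinely number in the
    millions); call :meth:`validate` or rely on the parsers, which always do.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    name: Optional[str] = None
    # extra attributes from peak dialects
    qvalue: Optional[float] = None
    pvalue: Optional[float] = None
    summit: Optional[int] = None  # offset from start; None if absent (-1 in file)

    def validate(self) -> "GenomicInterval":
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        return self

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeLayout:
    """Ordered chromosome name -> length map with an origin tag.

    Two layouts (``target`` and ``spikein``) together describe a dual-genome
    alignment; their chromosome names must be disjoint.
    """

    chrom_sizes: dict[str, int]
    origin: str = "target"

    def __post_init__(self) -> None:
        for name, length in self.chrom_sizes.items():
            if not name:
                raise ValueError("empty chromosome name in layout")
            if length <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chrom_sizes)

    def length(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.chrom_sizes[chrom] / bin_size)

    def check_disjoint(self, other: "GenomeLayout") -> None:
        shared = set(self.chrom_sizes) & set(other.chrom_sizes)
        if shared:
            raise ValueError(
                f"layouts {self.origin!r} and {other.origin!r} share chromosomes: {sorted(shared)}"
            )


@dataclass(slots=True)
class LibraryCounts:
    """Unique-read totals of one sequencing library, split by genome of origin."""

    target_unique_reads: int
    spikein_unique_reads: int

    def __post_init__(self) -> None:
        if self.target_unique_reads < 0 or self.spikein_unique_reads < 0:
            raise ValueError("read counts must be non-negative")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def _data_lines(handle: TextIO) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith(_SKIP_PREFIXES):
            continue
        yield lineno, line.split("\t")


def _check_layout(
    iv: GenomicInterval,
    layout: Optional[GenomeLayout],
    path,
    lineno: int,
    on_unknown_chrom: str,
) -> bool:
    """Return True if the interval should be kept."""
    if layout is None:
        return True
    if iv.chrom not in layout:
        if on_unknown_chrom == "skip":
            warnings.warn(
                f"{path}:{lineno}: chromosome {iv.chrom!r} not in layout "
                f"{layout.origin!r}; record skipped"
            )
            return False
        raise BedParseError(path, lineno, f"unknown chromosome {iv.chrom!r}")
    if iv.end > layout.length(iv.chrom):
        raise BedParseError(
            path,
            lineno,
            f"interval end {iv.end} beyond {iv.chrom} length {layout.length(iv.chrom)}",
        )
    return True


def read_bed(
    path: Union[str, Path],
    layout: Optional[GenomeLayout] = None,
    on_unknown_chrom: str = "error",
) -> list[GenomicInterval]:
    """Read a 3-6 column BED file, preserving record order.

    ``on_unknown_chrom`` is ``"error"`` (default) or ``"skip"``
    (skip-with-warning).
    """
    if on_unknown_chrom not in ("error", "skip"):
        raise ValueError("on_unknown_chrom must be 'error' or 'skip'")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if not 3 <= len(fields) <= 6:
                raise BedParseError(
                    path, lineno, f"expected 3-6 BED columns, got {len(fields)}"
                )
            try:
                iv = GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3] if len(fields) > 3 else None,
                    score=float(fields[4]) if len(fields) > 4 else None,
                    strand=fields[5] if len(fields) > 5 else ".",
                )
                iv.validate()
            except ValueError as exc:
                raise BedParseError(path, lineno, str(exc)) from exc
            if _check_layout(iv, layout, path, lineno, on_unknown_chrom):
                out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(f"{iv.score:g}" if iv.score is not None else "0")
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# ENCODE peak dialects
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = {"narrowPeak": 10, "broadPeak": 9}


def read_peaks(
    path: Union[str, Path],
    dialect: str,
    layout: Optional[GenomeLayout] = None,
    on_unknown_chrom: str = "error",
) -> list[GenomicInterval]:
    """Read MACS output in ENCODE narrowPeak (10 col) or broadPeak (9 col) layout.

    The signalValue column is mapped to ``score``; p/q columns (as stored in
    the file, conventionally -log10) are retained as ``pvalue`` / ``qvalue``
    attributes. A narrowPeak summit offset of -1 is recorded as absent.
    """
    if dialect not in _PEAK_COLUMNS:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    want = _PEAK_COLUMNS[dialect]
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) != want:
                raise BedParseError(
                    path,
                    lineno,
                    f"{dialect} requires {want} columns, got {len(fields)}",
                )
            try:
                iv = GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=None if fields[3] == "." else fields[3],
                    strand=fields[5] if fields[5] in STRANDS else ".",
                    score=float(fields[6]),  # signalValue
                    pvalue=float(fields[7]),
                    qvalue=float(fields[8]),
                )
                if dialect == "narrowPeak":
                    summit = int(fields[9])
                    iv.summit = None if summit < 0 else summit
                iv.validate()
            except BedParseError:
                raise
            except ValueError as exc:
                raise BedParseError(path, lineno, str(exc)) from exc
            if _check_layout(iv, layout, path, lineno, on_unknown_chrom):
                out.append(iv)
    return out


def write_broadpeak(intervals: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    """Write intervals as ENCODE broadPeak (9 columns)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name if iv.name is not None else f"peak_{i + 1}",
                        "0",
                        iv.strand,
                        f"{iv.score:g}" if iv.score is not None else "0",
                        f"{iv.pvalue:g}" if iv.pvalue is not None else "-1",
                        f"{iv.qvalue:g}" if iv.qvalue is not None else "-1",
                    ]
                )
                + "\n"
            )


def filter_peaks_by_qvalue(
    peaks: Sequence[GenomicInterval],
    cutoff: float = 0.05,
    keep: str = "significant",
    neglog10: bool = True,
) -> list[GenomicInterval]:
    """Filter peak/region calls on their q-value.

    ``keep="significant"`` retains regions with q <= cutoff (the conventional
    reading); ``keep="nonsignificant"`` retains q >= cutoff (the comparison
    direction is configurable because published pipelines disagree).
    ``neglog10`` says whether the stored qvalue attribute is -log10(q), the
    ENCODE file convention; if False it is a plain q-value.
    """
    if keep not in ("significant", "nonsignificant"):
        raise ValueError("keep must be 'significant' or 'nonsignificant'")
    out = []
    for p in peaks:
        if p.qvalue is None:
            raise ValueError("peak without q-value attribute cannot be filtered")
        q = 10.0 ** (-p.qvalue) if neglog10 else p.qvalue
        if (q <= cutoff) == (keep == "significant"):
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# bedGraph  (BinnedTrack I/O lives here to keep all format code in one place;
# the BinnedTrack type itself is defined in chorseq.coverage)
# ---------------------------------------------------------------------------


def write_bedgraph(track, path: Union[str, Path]) -> None:
    """Write a BinnedTrack as bedGraph, one line per bin, 6 significant digits.

    Bins are emitted in coordinate order per chromosome (they are stored that
    way); the final bin of a chromosome is clipped to the chromosome length.
    """
    with open(path, "w") as fh:
        for chrom in track.data:
            values = track.data[chrom]
            length = track.layout.length(chrom)
            bs = track.bin_size
            for i, v in enumerate(values):
                start = i * bs
                fh.write(f"{chrom}\t{start}\t{min(start + bs, length)}\t{v:.6g}\n")


def read_bedgraph(path: Union[str, Path], layout: GenomeLayout, bin_size: int):
    """Read a bedGraph produced by :func:`write_bedgraph` back into a BinnedTrack.

    Lines must be on the ``bin_size`` grid and sorted within each chromosome.
    """
    import numpy as np

    from .coverage import BinnedTrack

    data = {c: np.zeros(layout.n_bins(c, bin_size)) for c in layout}
    last_bin: dict[str, int] = {}
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) != 4:
                raise BedParseError(path, lineno, "bedGraph requires 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in layout:
                raise BedParseError(path, lineno, f"unknown chromosome {chrom!r}")
            if start % bin_size != 0:
                raise BedParseError(
                    path, lineno, f"start {start} not on the {bin_size} bp bin grid"
                )
            idx = start // bin_size
            if end not in (start + bin_size, layout.length(chrom)):
                raise BedParseError(path, lineno, f"bin [{start},{end}) has wrong width")
            if idx <= last_bin.get(chrom, -1):
                raise BedParseError(path, lineno, "bins out of order")
            last_bin[chrom] = idx
            data[chrom][idx] = value
    return BinnedTrack(bin_size=bin_size, data=data, layout=layout)


# ---------------------------------------------------------------------------
# chrom sizes
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: Union[str, Path], origin: str = "target") -> GenomeLayout:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) != 2:
                raise BedParseError(path, lineno, "chrom-sizes requires 2 columns")
            name, length = fields[0], int(fields[1])
            if name in sizes:
                raise BedParseError(path, lineno, f"duplicate chromosome {name!r}")
            sizes[name] = length
    return GenomeLayout(sizes, origin=origin)


def write_chrom_sizes(layout: GenomeLayout, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# dual-genome accounting
# ---------------------------------------------------------------------------


def split_by_genome(
    reads: Iterable[GenomicInterval],
    target: GenomeLayout,
    spikein: GenomeLayout,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Partition reads into (target, spike-in) by chromosome membership."""
    target.check_disjoint(spikein)
    t_reads: list[GenomicInterval] = []
    s_reads: list[GenomicInterval] = []
    t_names = set(target.chrom_sizes)
    s_names = set(spikein.chrom_sizes)
    for r in reads:
        if r.chrom in t_names:
            t_reads.append(r)
        elif r.chrom in s_names:
            s_reads.append(r)
        else:
            raise ValueError(f"read on chromosome {r.chrom!r} not in either layout")
    return t_reads, s_reads


def count_library(
    reads: Iterable[GenomicInterval],
    target: GenomeLayout,
    spikein: GenomeLayout,
) -> LibraryCounts:
    """Library totals by genome of origin (the RRPM denominator source)."""
    t_reads, s_reads = split_by_genome(reads, target, spikein)
    return LibraryCounts(len(t_reads), len(s_reads))
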