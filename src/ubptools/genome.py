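"""Coordinate conventions and interval algebra.

All coordinates are 0-based, half-open (BED convention). 1-based inclusive
inputs (RepeatMasker-style tables) are converted by the readers in
:mod:`ubptools.io_tables`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open.

    ``strand`` is "+", "-" or "." (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """True iff the intervals share >= 1 base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


class GenomeSpec:
    """Chromosome names and lengths defining the coordinate space.

    Also provides a concatenated ("absolute") coordinate system used by the
    vectorized shuffle and overlap machinery: chromosome ``i`` occupies
    absolute positions ``[offset[i], offset[i] + length[i])``.
    """

    def __init__(self, chrom_names: Sequence[str], chrom_lengths: Sequence[int]):
        names = list(chrom_names)
        lengths = [int(x) for x in chrom_lengths]
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")
        self.chrom_names = names
        self.chrom_lengths = np.asarray(lengths, dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.chrom_lengths)])
        self._index = {c: i for i, c in enumerate(names)}

    def __len__(self) -> int:
        return len(self.chrom_names)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeSpec)
            and self.chrom_names == other.chrom_names
            and bool(np.array_equal(self.chrom_lengths, other.chrom_lengths))
        )

    @property
    def total_length(self) -> int:
        return int(self.offsets[-1])

    def length_of(self, chrom: str) -> int:
        return int(self.chrom_lengths[self._index[chrom]])

    def chrom_index(self, chrom: str) -> int:
        return self._index[chrom]

    def validate_interval(self, iv: Interval) -> None:
        if iv.chrom not in self._index:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.length_of(iv.chrom):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.length_of(iv.chrom)}"
            )

    def to_absolute(self, intervals: Iterable[Interval]):
        """Map intervals to absolute coordinates; returns (starts, ends) arrays."""
        starts, ends = [], []
        for iv in intervals:
            off = self.offsets[self._index[iv.chrom]]
            starts.append(off + iv.start)
            ends.append(off + iv.end)
        return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)

    def from_absolute(self, abs_starts, abs_ends, strands=None) -> list[Interval]:
        abs_starts = np.asarray(abs_starts, dtype=np.int64)
        abs_ends = np.asarray(abs_ends, dtype=np.int64)
        chrom_idx = np.searchsorted(self.offsets, abs_starts, side="right") - 1
        out = []
        for i, (s, e, ci) in enumerate(zip(abs_starts, abs_ends, chrom_idx)):
            off = self.offsets[ci]
            strand = strands[i] if strands is not None else "."
            out.append(Interval(self.chrom_names[ci], int(s - off), int(e - off), strand))
        return out


def union_merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or bookended intervals into a sorted disjoint set.

    Bookended intervals (end == next start) are merged; strand is dropped.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    if not by_chrom:
        return []
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(Interval(chrom, cur_s, cur_e))
    return merged


def overlap_bp(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    """Total base pairs shared between the unions of two interval sets."""
    a, b = list(a), list(b)
    if not a or not b:
        return 0
    ma, mb = union_merge(a), union_merge(b)
    total = 0
    # group merged intervals per chromosome and sweep
    ga: dict[str, list[Interval]] = {}
    gb: dict[str, list[Interval]] = {}
    for iv in ma:
        ga.setdefault(iv.chrom, []).append(iv)
    for iv in mb:
        gb.setdefault(iv.chrom, []).append(iv)
    for chrom in ga.keys() & gb.keys():
        xs, ys = ga[chrom], gb[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                total += e - s
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return total


class IntervalIndex:
    """Merged interval set with prefix sums of covered bases.

    Supports O(log n) vectorized coverage queries in absolute coordinates,
    used by the shuffle machinery and the permutation overlap computation.
    """

    def __init__(self, intervals: Iterable[Interval], genome: GenomeSpec):
        self.genome = genome
        merged = union_merge(list(intervals))
        for iv in merged:
            genome.validate_interval(iv)
        if merged:
            s, e = genome.to_absolute(merged)
            order = np.argsort(s)
            self.abs_starts = s[order]
            self.abs_ends = e[order]
        else:
            self.abs_starts = np.empty(0, dtype=np.int64)
            self.abs_ends = np.empty(0, dtype=np.int64)
        self.cum = np.concatenate(
            [[0], np.cumsum(self.abs_ends - self.abs_starts)]
        )
        self.intervals = merged

    @property
    def total_bases(self) -> int:
        return int(self.cum[-1])

    def prefix(self, x):
        """Covered bases in absolute range [0, x); vectorized in x."""
        x = np.asarray(x, dtype=np.int64)
        i = np.searchsorted(self.abs_starts, x, side="right") - 1
        i_clip = np.maximum(i, 0)
        within = np.clip(x - self.abs_starts[i_clip], 0,
                         self.abs_ends[i_clip] - self.abs_starts[i_clip])
        return np.where(i < 0, 0, self.cum[i_clip] + within)

    def coverage(self, abs_start, abs_end):
        """Covered bases inside [abs_start, abs_end); vectorized."""
        return self.prefix(abs_end) - self.prefix(abs_start)


@dataclass
class Peak:
    """A scored peak interval with per-sample RPKM values."""

    interval: Interval
    id: str
    rpkm_by_sample: Mapping[str, float] = field(default_factory=dict)
    auc: float | None = None

    def __post_init__(self) -> None:
        for sample, value in self.rpkm_by_sample.items():
            if value < 0:
                raise ValueError(f"negative RPKM for {self.id}/{sample}")


class PeakSet:
    """Ordered collection of peaks bound to a genome."""

    def __init__(self, peaks: Sequence[Peak], genome: GenomeSpec):
        for p in peaks:
            genome.validate_interval(p.interval)
        ids = [p.id for p in peaks]
        if len(set(ids)) != len(ids):
            raise ValueError("peak ids must be unique")
        self.peaks = list(peaks)
        self.genome = genome

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def intervals(self) -> list[Interval]:
        return [p.interval for p in self.peaks]

    def rpkm(self, sample: str) -> dict[str, float]:
        return {p.id: p.rpkm_by_sample[sample] for p in self.peaks}


@dataclass
class Blacklist:
    """Intervals excluded from analysis (artifact-prone regions)."""

    intervals: list[Interval]

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class GeneModel:
    """A gene summarized by its TSS/TES; both are strand-resolved coordinates."""

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: TSS equals TES")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def body(self) -> Interval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return Interval(self.chrom, lo, hi, self.strand)


class TEAnnotation:
    """Transposable-element insertions tagged by subclass and subfamily."""

    SUBCLASSES = {"LINE", "LTR", "SINE", "DNA", "other"}

    def __init__(self, records: Iterable[tuple[Interval, str, str]]):
        recs = []
        for iv, subclass, subfamily in records:
            if not subclass or not subfamily:
                raise ValueError("empty TE subclass or subfamily")
            recs.append((iv, subclass, subfamily))
        self.records = recs

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def subfamilies(self) -> set[str]:
        return {sf for _, _, sf in self.records}

    @property
    def subclasses(self) -> set[str]:
        return {sc for _, sc, _ in self.records}

    def intervals_of(self, *, subfamily: str | None = None,
                     subclass: str | None = None) -> list[Interval]:
        out = []
        for iv, sc, sf in self.records:
            if subfamily is not None and sf != subfamily:
                continue
            if subclass is not None and sc != subclass:
                continue
            out.append(iv)
        return out
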