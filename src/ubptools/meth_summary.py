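"""WCG/GCH cytosine-context calling and region-level methylation summaries.

WCG (W = A or T) sites report endogenous CpG methylation; GCH (H = A, T or C)
sites report GpC-methyltransferase-marked chromatin accessibility. GCG is
ambiguous between the two and is excluded ("other"). Minus-strand cytosines
are evaluated on the reverse complement of the plus-strand trinucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec, Interval, union_merge

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

W = {"A", "T"}
H = {"A", "T", "C"}


def _trinucleotide(seq: str, position: int, strand: str) -> str:
    if position < 1 or position > len(seq) - 2:
        raise ValueError(f"position {position} lacks a one-base flank")
    tri = seq[position - 1 : position + 2].upper()
    if strand == "-":
        tri = tri.translate(_COMPLEMENT)[::-1]
    elif strand != "+":
        raise ValueError(f"strand must be + or -, got {strand!r}")
    return tri


def classify_trinucleotide(tri: str) -> str:
    """Context of a trinucleotide whose middle base is C: WCG, GCH or other."""
    if len(tri) != 3 or tri[1] != "C":
        raise ValueError(f"no cytosine at the center of {tri!r}")
    if tri[0] in W and tri[2] == "G":
        return "WCG"
    if tri[0] == "G" and tri[2] in H:
        return "GCH"
    return "other"


def call_context(ref_seq: str, position: int, strand: str = "+") -> str:
    """Context of the cytosine at ``position`` on ``strand`` of ``ref_seq``."""
    tri = _trinucleotide(ref_seq, position, strand)
    return classify_trinucleotide(tri)


def find_context_sites(seq: str, context: str | None = None) -> pd.DataFrame:
    """All cytosine sites on both strands with their context.

    Returns columns pos (0-based plus-strand coordinate of the cytosine),
    strand and context; optionally restricted to one context.
    """
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    rows = []
    c_plus = np.flatnonzero(arr == ord("C"))
    c_minus = np.flatnonzero(arr == ord("G"))  # C on the minus strand
    for positions, strand in ((c_plus, "+"), (c_minus, "-")):
        for pos in positions:
            if pos < 1 or pos > len(seq) - 2:
                continue
            ctx = call_context(seq, int(pos), strand)
            if context is None or ctx == context:
                rows.append((int(pos), strand, ctx))
    return pd.DataFrame(rows, columns=["pos", "strand", "context"])


@dataclass
class RegionMethLevel:
    """Methylation level of one region in one context."""

    region: Interval | None
    context: str
    n_meth: int
    n_total: int

    @property
    def level(self) -> float | None:
        if self.n_total == 0:
            return None
        return self.n_meth / self.n_total


def region_level(calls: pd.DataFrame, region: Interval, context: str) -> RegionMethLevel:
    """Aggregate methylated/total call counts inside one region.

    ``calls`` needs columns chrom, pos, context, methylated. A region with no
    covered sites yields n_total = 0 and ``level is None``.
    """
    sub = calls[
        (calls["chrom"] == region.chrom)
        & (calls["pos"] >= region.start)
        & (calls["pos"] < region.end)
        & (calls["context"] == context)
    ]
    return RegionMethLevel(region, context, int(sub["methylated"].sum()), len(sub))


def tile_levels(
    calls: pd.DataFrame,
    genome: GenomeSpec,
    context: str,
    tile: int = 1000,
    min_sites: int = 3,
    breakpoints: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
) -> pd.DataFrame:
    """Per-tile methylation levels with a categorical (binned) label.

    Tiles partition each chromosome; tiles with fewer than ``min_sites``
    calls are excluded. Categories are half-open bins of the level at the
    configurable breakpoints, with 1.0 folded into the top bin.
    """
    if tile <= 0:
        raise ValueError("tile size must be positive")
    sub = calls[calls["context"] == context]
    rows = []
    edges = (0.0, *breakpoints, 1.0)
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels[-1] = labels[-1][:-1] + "]"
    for chrom in genome.chrom_names:
        chrom_calls = sub[sub["chrom"] == chrom]
        if chrom_calls.empty:
            continue
        tile_idx = (chrom_calls["pos"] // tile).to_numpy()
        meth = chrom_calls["methylated"].to_numpy()
        for t in np.unique(tile_idx):
            mask = tile_idx == t
            n_total = int(mask.sum())
            if n_total < min_sites:
                continue
            n_meth = int(meth[mask].sum())
            level = n_meth / n_total
            cat = min(int(np.searchsorted(breakpoints, level, side="right")), len(labels) - 1)
            start = int(t) * tile
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": min(start + tile, genome.length_of(chrom)),
                    "context": context,
                    "n_meth": n_meth,
                    "n_total": n_total,
                    "level": level,
                    "category": labels[cat],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "n_meth", "n_total", "level", "category"],
    )


def aggregate_embryos(call_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-embryo call tables; downstream levels become pooled counts."""
    if not call_sets:
        raise ValueError("no call sets to aggregate")
    return pd.concat(call_sets, ignore_index=True)


def feature_meth(
    calls: pd.DataFrame,
    features: dict[str, list[Interval]],
    context: str,
) -> pd.DataFrame:
    """Pooled methylation level per named feature (insertions merged first)."""
    rows = []
    for name, intervals in features.items():
        n_meth = n_total = 0
        for iv in union_merge(intervals) if intervals else []:
            lev = region_level(calls, iv, context)
            n_meth += lev.n_meth
            n_total += lev.n_total
        rows.append(
            {
                "feature": name,
                "context": context,
                "n_meth": n_meth,
                "n_total": n_total,
                "level": n_meth / n_total if n_total else np.nan,
            }
        )
    return pd.DataFrame(rows)
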