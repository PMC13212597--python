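"""Summit windows, GC/length-matched backgrounds and motif-hit filtering.

For motif analysis each selected peak contributes a 200-bp window centered on
its point of maximal signal. Background regions are drawn from a caller-
supplied pool (e.g. other TE subfamilies of the same class), matched to the
targets in number, length (pool regions are center-trimmed to the window
width) and GC content (exact per-bin matching at a configurable bin width),
sampling without replacement. Motif-enrichment hits from an external scanner
are filtered on expression rank, enrichment score and E-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec, Interval, IntervalIndex, PeakSet, TEAnnotation

WINDOW = 200


@dataclass
class MotifRegion:
    """A fixed-width window with its sequence and GC fraction."""

    source_id: str
    window: Interval
    sequence: str | None = None
    gc: float | None = None
    clamped: bool = False


def gc_content(seq: str) -> float:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def summit_window(
    peak_interval: Interval,
    signal,
    genome: GenomeSpec,
    sequences: dict[str, str] | None = None,
    source_id: str = "",
    width: int = WINDOW,
) -> MotifRegion:
    """Window of ``width`` bp centered on the peak's signal maximum.

    ``signal`` is the per-base signal across the peak (length = peak length).
    Ties take the leftmost maximum. Windows running past a chromosome end are
    shifted back inside (flagged as clamped); a chromosome shorter than the
    window yields the whole chromosome, flagged.
    """
    sig = np.asarray(signal, dtype=float)
    if sig.size == 0:
        raise ValueError("empty signal profile")
    if sig.size != peak_interval.length:
        raise ValueError("signal length must equal peak length")
    summit = peak_interval.start + int(np.argmax(sig))
    half = width // 2
    chrom_len = genome.length_of(peak_interval.chrom)
    start, end = summit - half, summit + (width - half)
    clamped = False
    if start < 0:
        start, end, clamped = 0, min(width, chrom_len), True
    elif end > chrom_len:
        start, end, clamped = max(0, chrom_len - width), chrom_len, True
    window = Interval(peak_interval.chrom, start, end)
    seq = gc = None
    if sequences is not None:
        seq = sequences[window.chrom][window.start : window.end]
        gc = gc_content(seq)
    return MotifRegion(source_id, window, seq, gc, clamped)


def intersect_ubps_with_subtypes(
    ubps,
    te: TEAnnotation,
    subtypes: list[str],
    genome: GenomeSpec,
) -> list[Interval]:
    """UBP intervals with >= 1 bp overlap to any of the listed TE subtypes."""
    unknown = [s for s in subtypes if s not in te.subfamilies]
    if unknown:
        raise ValueError(f"unknown TE subtypes: {unknown}")
    pooled = []
    for s in subtypes:
        pooled.extend(te.intervals_of(subfamily=s))
    index = IntervalIndex(pooled, genome)
    intervals = ubps.intervals if isinstance(ubps, PeakSet) else list(ubps)
    out = []
    for iv in intervals:
        s, e = genome.to_absolute([iv])
        if int(index.coverage(s, e)[0]) > 0:
            out.append(iv)
    return out


def _center_trim(iv: Interval, width: int) -> Interval:
    if iv.length <= width:
        return iv
    mid = (iv.start + iv.end) // 2
    start = mid - width // 2
    return Interval(iv.chrom, start, start + width, iv.strand)


def sample_matched_background(
    targets: list[MotifRegion],
    pool: list[Interval],
    genome: GenomeSpec,
    sequences: dict[str, str],
    seed: int | np.random.Generator | None = None,
    bin_width: float = 0.05,
    width: int = WINDOW,
) -> list[MotifRegion]:
    """Background regions GC-matched to the targets, bin-exactly.

    Pool regions longer than ``width`` are center-trimmed to ``width`` before
    GC computation so lengths match the targets. For every GC bin (width
    ``bin_width``) the background receives exactly as many regions as the
    targets have in that bin, sampled without replacement from the pool;
    an under-populated bin raises an error naming the bin.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if any(t.gc is None for t in targets):
        raise ValueError("targets need GC values (build them with sequences)")
    n_bins = int(np.ceil(1.0 / bin_width))

    def bin_of(gc: float) -> int:
        return min(int(gc / bin_width), n_bins - 1)

    target_bins: dict[int, int] = {}
    for t in targets:
        target_bins[bin_of(t.gc)] = target_bins.get(bin_of(t.gc), 0) + 1

    pool_by_bin: dict[int, list[MotifRegion]] = {}
    for i, iv in enumerate(pool):
        trimmed = _center_trim(iv, width)
        seq = sequences[trimmed.chrom][trimmed.start : trimmed.end]
        gc = gc_content(seq)
        pool_by_bin.setdefault(bin_of(gc), []).append(
            MotifRegion(f"bg_{i}", trimmed, seq, gc)
        )

    background: list[MotifRegion] = []
    for b in sorted(target_bins):
        need = target_bins[b]
        have = pool_by_bin.get(b, [])
        if len(have) < need:
            lo, hi = b * bin_width, (b + 1) * bin_width
            raise ValueError(
                f"GC bin [{lo:.2f},{hi:.2f}) has {len(have)} pool regions, "
                f"need {need}"
            )
        chosen = rng.choice(len(have), size=need, replace=False)
        background.extend(have[int(j)] for j in chosen)
    return background


def filter_motif_hits(
    hits: pd.DataFrame,
    expression: dict[str, float],
    min_score: float = 2.0,
    max_e: float = 1e-10,
    top_fraction: float = 0.5,
) -> pd.DataFrame:
    """Keep hits whose gene sits in the top expression fraction and which pass
    the score/E-value cuts (both strict).

    Ranking uses the supplied expression table after removing zero-expression
    genes; ties at the cutoff are retained. Hits whose gene is absent from the
    table raise an error listing the genes.
    """
    required = ["motif", "gene", "score", "e_value"]
    missing_cols = [c for c in required if c not in hits.columns]
    if missing_cols:
        raise ValueError(f"hits table missing columns {missing_cols}")
    missing = sorted(set(hits["gene"]) - set(expression))
    if missing:
        raise KeyError(f"genes missing from expression table: {missing}")
    values = np.array([v for v in expression.values() if v > 0], dtype=float)
    if values.size == 0:
        raise ValueError("expression table has no expressed genes")
    cutoff = float(np.quantile(values, 1.0 - top_fraction))
    keep = (
        hits["gene"].map(expression).ge(cutoff)
        & (hits["score"] > min_score)
        & (hits["e_value"] < max_e)
    )
    return hits[keep].reset_index(drop=True)
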