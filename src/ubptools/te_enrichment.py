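"""Permutation-based enrichment of region sets at transposable elements.

The null model re-places the query regions uniformly at random across the
genome, preserving their number and lengths and avoiding an exclusion set
(e.g. a blacklist). Enrichment is the observed base-pair overlap with a
merged TE interval set divided by the mean overlap across permutations; the
empirical P value is (k+1)/(N+1), where k counts permutations whose overlap
is greater than or equal to the observed value.

Placement law: a chromosome is chosen with probability proportional to the
number of feasible start positions for the region's length, then the start is
uniform among those positions; regions may land on any chromosome and may
overlap each other. Placements touching the exclusion set are rejected and
redrawn (retry cap per region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Blacklist, GenomeSpec, Interval, IntervalIndex, TEAnnotation, union_merge


def build_te_universe(te: TEAnnotation, group_by: str = "subclass") -> dict[str, list[Interval]]:
    """Merge TE insertions per subclass or subfamily into disjoint intervals."""
    if len(te) == 0:
        raise ValueError("empty TE annotation")
    if group_by == "subclass":
        labels = sorted(te.subclasses)
        return {lb: union_merge(te.intervals_of(subclass=lb)) for lb in labels}
    if group_by == "subfamily":
        labels = sorted(te.subfamilies)
        return {lb: union_merge(te.intervals_of(subfamily=lb)) for lb in labels}
    raise ValueError(f"unknown grouping {group_by!r} (use 'subclass' or 'subfamily')")


def _exclusion_index(genome: GenomeSpec, exclude) -> IntervalIndex | None:
    if exclude is None:
        return None
    intervals = list(exclude.intervals if isinstance(exclude, Blacklist) else exclude)
    if not intervals:
        return None
    return IntervalIndex(intervals, genome)


def _sample_placements(
    rng: np.random.Generator,
    lengths: np.ndarray,
    genome: GenomeSpec,
    exclude_index: IntervalIndex | None,
    max_retries: int = 1000,
) -> np.ndarray:
    """Vectorized placement of regions; returns absolute start positions."""
    lengths = np.asarray(lengths, dtype=np.int64)
    m = lengths.size
    # feasible start positions per (region, chromosome)
    feas = np.clip(genome.chrom_lengths[None, :] - lengths[:, None] + 1, 0, None)
    totals = feas.sum(axis=1)
    if np.any(totals == 0):
        bad = int(np.argmax(totals == 0))
        raise ValueError(
            f"region of length {int(lengths[bad])} does not fit on any chromosome"
        )
    cdf = np.cumsum(feas, axis=1)

    def draw(idx: np.ndarray) -> np.ndarray:
        u = rng.random(idx.size) * totals[idx]
        ci = (u[:, None] >= cdf[idx]).sum(axis=1)
        pos = rng.integers(0, feas[idx, ci])
        return genome.offsets[ci] + pos

    starts = draw(np.arange(m))
    if exclude_index is None:
        return starts
    pending = np.flatnonzero(exclude_index.coverage(starts, starts + lengths) > 0)
    retries = 0
    while pending.size:
        retries += 1
        if retries > max_retries:
            raise RuntimeError(
                f"could not place region of length {int(lengths[pending[0]])} "
                f"outside the exclusion set after {max_retries} retries"
            )
        starts[pending] = draw(pending)
        bad = exclude_index.coverage(
            starts[pending], starts[pending] + lengths[pending]
        ) > 0
        pending = pending[bad]
    return starts


def shuffle_regions(
    regions,
    genome: GenomeSpec,
    exclude=None,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 1000,
) -> list[Interval]:
    """Randomly re-place regions, preserving count and the length multiset."""
    regions = list(regions)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for iv in regions:
        genome.validate_interval(iv)
    lengths = np.array([iv.length for iv in regions], dtype=np.int64)
    if lengths.size == 0:
        return []
    starts = _sample_placements(rng, lengths, genome, _exclusion_index(genome, exclude), max_retries)
    return genome.from_absolute(starts, starts + lengths)


def _union_overlap_rows(starts: np.ndarray, lengths: np.ndarray, index: IntervalIndex) -> np.ndarray:
    """Per-row base-pair overlap between the union of row intervals and ``index``.

    ``starts`` has shape (P, n) in absolute coordinates; ``lengths`` broadcasts
    against it. Row intervals may overlap each other; overlapped bases are
    counted once (union semantics, matching ``overlap_bp`` on merged sets).
    """
    ends = starts + lengths
    order = np.argsort(starts, axis=1, kind="stable")
    s = np.take_along_axis(starts, order, axis=1)
    e = np.take_along_axis(ends, order, axis=1)
    cummax = np.maximum.accumulate(e, axis=1)
    prev = np.empty_like(cummax)
    prev[:, 0] = 0
    prev[:, 1:] = cummax[:, :-1]
    eff_s = np.maximum(s, prev)
    contrib = index.prefix(e) - index.prefix(np.minimum(eff_s, e))
    return np.clip(contrib, 0, None).sum(axis=1)


@dataclass
class EnrichmentResult:
    """Outcome of one permutation enrichment test against one TE label."""

    te_label: str
    observed_overlap: int
    perm_mean: float
    odds_ratio: float
    k: int
    p: float
    n_perm: int
    perm_overlaps: np.ndarray | None = field(default=None, repr=False)


def empirical_p(observed: float, perm_overlaps: np.ndarray) -> tuple[int, float]:
    """(k, p) with k = #{permutations >= observed}, p = (k+1)/(N+1)."""
    perm_overlaps = np.asarray(perm_overlaps)
    k = int(np.sum(perm_overlaps >= observed))
    return k, (k + 1) / (perm_overlaps.size + 1)


def permutation_enrichment(
    regions,
    te_intervals,
    genome: GenomeSpec,
    exclude=None,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    te_label: str = "TE",
    keep_perms: bool = True,
    max_retries: int = 1000,
    chunk: int = 256,
) -> EnrichmentResult:
    """Permutation test of region overlap with one merged TE interval set."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    regions = list(regions)
    if not regions:
        raise ValueError("empty region set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for iv in regions:
        genome.validate_interval(iv)
    te_index = IntervalIndex(te_intervals, genome)
    ex_index = _exclusion_index(genome, exclude)

    lengths = np.array([iv.length for iv in regions], dtype=np.int64)
    n = lengths.size
    obs_starts, _ = genome.to_absolute(regions)
    observed = int(_union_overlap_rows(obs_starts[None, :], lengths[None, :], te_index)[0])

    perm_overlaps = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        p = min(chunk, n_perm - done)
        tiled = np.tile(lengths, p)
        starts = _sample_placements(rng, tiled, genome, ex_index, max_retries)
        perm_overlaps[done : done + p] = _union_overlap_rows(
            starts.reshape(p, n), lengths[None, :], te_index
        )
        done += p

    perm_mean = float(perm_overlaps.mean())
    if perm_mean == 0:
        warnings.warn(
            f"{te_label}: mean permuted overlap is 0; odds ratio undefined (+inf)",
            RuntimeWarning,
            stacklevel=2,
        )
        odds_ratio = float("inf") if observed > 0 else float("nan")
    else:
        odds_ratio = observed / perm_mean
    k, p_val = empirical_p(observed, perm_overlaps)
    return EnrichmentResult(
        te_label=te_label,
        observed_overlap=observed,
        perm_mean=perm_mean,
        odds_ratio=odds_ratio,
        k=k,
        p=p_val,
        n_perm=n_perm,
        perm_overlaps=perm_overlaps if keep_perms else None,
    )


def enrichment_table(
    regions,
    te: TEAnnotation,
    genome: GenomeSpec,
    group_by: str = "subclass",
    exclude=None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the permutation test against every TE label; one row per label."""
    rng = np.random.default_rng(seed)
    universe = build_te_universe(te, group_by)
    rows = []
    for label, te_intervals in universe.items():
        res = permutation_enrichment(
            regions, te_intervals, genome, exclude=exclude, n_perm=n_perm,
            seed=rng, te_label=label, keep_perms=False,
        )
        rows.append(
            {
                "te_label": res.te_label,
                "observed_overlap": res.observed_overlap,
                "perm_mean": res.perm_mean,
                "odds_ratio": res.odds_ratio,
                "k": res.k,
                "p": res.p,
                "n_perm": res.n_perm,
            }
        )
    return pd.DataFrame(rows)
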