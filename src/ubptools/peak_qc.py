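"""Peak-retention filters for ATAC, H3K9me3 and UHRF1 peak sets.

ATAC peaks are kept when supported by both replicates (>= 1 bp overlap),
longer than 100 bp, with mean replicate RPKM above 50 and less than a 2-fold
RPKM difference between replicates. H3K9me3-style sets require support in all
replicates. UHRF1-style sets additionally require treatment RPKM strictly
above the Input. Peaks touching the blacklist are excluded everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .genome import Blacklist, IntervalIndex, Peak, PeakSet


class FailReason(str, Enum):
    NO_REPLICATE_SUPPORT = "no_replicate_support"
    LENGTH = "length"
    LOW_RPKM = "low_rpkm"
    REPLICATE_DISCORDANCE = "replicate_discordance"
    NOT_IN_ALL_REPLICATES = "not_in_all_replicates"
    NOT_ABOVE_INPUT = "not_above_input"
    BLACKLIST = "blacklist"


@dataclass
class QcReport:
    """Per-peak pass/fail bookkeeping; one row per input peak."""

    table: pd.DataFrame  # columns: peak_id, retained, reason

    @property
    def n_in(self) -> int:
        return len(self.table)

    @property
    def n_retained(self) -> int:
        return int(self.table["retained"].sum())

    def counts_by_reason(self) -> dict[str, int]:
        removed = self.table[~self.table["retained"]]
        return removed["reason"].value_counts().to_dict()


def _overlaps_any(peak: Peak, index: IntervalIndex, genome) -> bool:
    s, e = genome.to_absolute([peak.interval])
    return int(index.coverage(s, e)[0]) > 0


def qc_atac(
    rep1: PeakSet,
    rep2: PeakSet,
    rpkm_rep1: dict[str, float] | None = None,
    rpkm_rep2: dict[str, float] | None = None,
    min_len: int = 100,
    min_rpkm: float = 50.0,
    max_fold: float = 2.0,
    rpkm_samples: tuple[str, str] | None = None,
) -> tuple[PeakSet, QcReport]:
    """Replicate-concordance filter for ATAC peaks; coordinates from rep1.

    Replicate RPKMs come either from the ``rpkm_rep1``/``rpkm_rep2`` mappings
    (peak id -> RPKM, both evaluated on rep1 coordinates) or from each peak's
    ``rpkm_by_sample`` under the two names in ``rpkm_samples``. The retention
    rule: >= 1 bp overlap with a rep2 peak, length strictly greater than
    ``min_len``, mean replicate RPKM > ``min_rpkm`` and max/min replicate
    ratio < ``max_fold``. The failure reason recorded per removed peak is the
    first failing rule in that order.
    """
    if rep1.genome != rep2.genome:
        raise ValueError("replicates are on different genomes")
    genome = rep1.genome
    rep2_index = IntervalIndex(rep2.intervals, genome) if len(rep2) else None

    def replicate_rpkms(p: Peak) -> tuple[float, float]:
        if rpkm_rep1 is not None and rpkm_rep2 is not None:
            try:
                return rpkm_rep1[p.id], rpkm_rep2[p.id]
            except KeyError as exc:
                raise ValueError(f"missing replicate RPKM for peak {p.id}") from exc
        if rpkm_samples is not None:
            try:
                return (p.rpkm_by_sample[rpkm_samples[0]], p.rpkm_by_sample[rpkm_samples[1]])
            except KeyError as exc:
                raise ValueError(f"missing replicate RPKM for peak {p.id}") from exc
        raise ValueError("provide rpkm_rep1/rpkm_rep2 mappings or rpkm_samples names")

    rows, kept = [], []
    for p in rep1:
        r1, r2 = replicate_rpkms(p)
        reason = None
        if rep2_index is None or not _overlaps_any(p, rep2_index, genome):
            reason = FailReason.NO_REPLICATE_SUPPORT
        elif p.interval.length <= min_len:
            reason = FailReason.LENGTH
        elif (r1 + r2) / 2 <= min_rpkm:
            reason = FailReason.LOW_RPKM
        elif min(r1, r2) == 0 or max(r1, r2) / min(r1, r2) >= max_fold:
            reason = FailReason.REPLICATE_DISCORDANCE
        rows.append({"peak_id": p.id, "retained": reason is None,
                     "reason": None if reason is None else reason.value})
        if reason is None:
            kept.append(p)
    return PeakSet(kept, genome), QcReport(pd.DataFrame(rows, columns=["peak_id", "retained", "reason"]))


def qc_all_replicates(peaksets: list[PeakSet]) -> tuple[PeakSet, QcReport]:
    """Keep rep-1 peaks that overlap >= 1 peak in every other replicate."""
    if len(peaksets) < 2:
        raise ValueError("need at least two replicates")
    genome = peaksets[0].genome
    for ps in peaksets[1:]:
        if ps.genome != genome:
            raise ValueError("replicates are on different genomes")
    others = [IntervalIndex(ps.intervals, genome) if len(ps) else None for ps in peaksets[1:]]
    rows, kept = [], []
    for p in peaksets[0]:
        ok = all(idx is not None and _overlaps_any(p, idx, genome) for idx in others)
        rows.append({"peak_id": p.id, "retained": ok,
                     "reason": None if ok else FailReason.NOT_IN_ALL_REPLICATES.value})
        if ok:
            kept.append(p)
    return PeakSet(kept, genome), QcReport(pd.DataFrame(rows, columns=["peak_id", "retained", "reason"]))


def qc_vs_input(
    peaks: PeakSet,
    treatment_rpkm: dict[str, float],
    input_rpkm: dict[str, float],
) -> tuple[PeakSet, QcReport]:
    """Keep peaks whose treatment RPKM strictly exceeds the Input RPKM."""
    rows, kept = [], []
    for p in peaks:
        try:
            t, i = treatment_rpkm[p.id], input_rpkm[p.id]
        except KeyError as exc:
            raise ValueError(f"missing RPKM for peak {p.id}") from exc
        ok = t > i
        rows.append({"peak_id": p.id, "retained": ok,
                     "reason": None if ok else FailReason.NOT_ABOVE_INPUT.value})
        if ok:
            kept.append(p)
    return PeakSet(kept, peaks.genome), QcReport(pd.DataFrame(rows, columns=["peak_id", "retained", "reason"]))


def apply_blacklist(peaks: PeakSet, blacklist: Blacklist) -> tuple[PeakSet, QcReport]:
    """Remove peaks sharing >= 1 bp with the blacklist."""
    index = IntervalIndex(list(blacklist), peaks.genome) if len(blacklist) else None
    rows, kept = [], []
    for p in peaks:
        hit = index is not None and _overlaps_any(p, index, peaks.genome)
        rows.append({"peak_id": p.id, "retained": not hit,
                     "reason": FailReason.BLACKLIST.value if hit else None})
        if not hit:
            kept.append(p)
    return PeakSet(kept, peaks.genome), QcReport(pd.DataFrame(rows, columns=["peak_id", "retained", "reason"]))


def top_fraction_by_auc(peaks: PeakSet, fraction: float = 0.01) -> PeakSet:
    """Optional re-application of a top-AUC cut (e.g. top 1% of regions)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scored = [p for p in peaks if p.auc is not None]
    if len(scored) != len(peaks):
        raise ValueError("every peak needs an AUC value for the top-AUC cut")
    n_keep = max(1, int(round(fraction * len(scored))))
    kept = sorted(scored, key=lambda p: -p.auc)[:n_keep]
    keep_ids = {p.id for p in kept}
    return PeakSet([p for p in peaks if p.id in keep_ids], peaks.genome)
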