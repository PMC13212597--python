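"""Merging, ratio classification and annotation of UHRF1 binding peaks (UBPs).

WT and knockout peak sets are merged into a single UBP universe; each merged
interval is classified by the KO-to-WT mean-RPKM ratio: primitive
(0.8 <= ratio < 1.2), enhanced (ratio >= 1.2), reduced (ratio < 0.8, kept but
excluded from downstream enrichment by default), or unclassifiable when the
WT RPKM is zero. Peaks are annotated with one primary genomic feature
(promoter > genebody > intergenic) and all overlapping TE subfamilies.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GeneModel,
    GenomeSpec,
    Interval,
    IntervalIndex,
    PeakSet,
    TEAnnotation,
    union_merge,
)
from .stats import fisher_exact_2x2

PRIMITIVE = "primitive"
ENHANCED = "enhanced"
REDUCED = "reduced"
UNCLASSIFIABLE = "unclassifiable"

PROMOTER = "promoter"
GENEBODY = "genebody"
INTERGENIC = "intergenic"


def merge_condition_peaks(wt: PeakSet, ko: PeakSet) -> list[Interval]:
    """Union-merge the WT and KO peak sets into one UBP universe."""
    if wt.genome != ko.genome:
        raise ValueError("WT and KO peak sets are on different genomes")
    return union_merge(wt.intervals + ko.intervals)


def classify_ratio(ratio: float, lower: float = 0.8, upper: float = 1.2) -> str:
    if ratio >= upper:
        return ENHANCED
    if ratio >= lower:
        return PRIMITIVE
    return REDUCED


def classify_ubps(
    merged: Sequence[Interval],
    wt_rpkm: Sequence[float],
    ko_rpkm: Sequence[float],
    lower: float = 0.8,
    upper: float = 1.2,
) -> pd.DataFrame:
    """Classify merged UBP intervals by the KO/WT RPKM ratio.

    ``wt_rpkm``/``ko_rpkm`` are condition-level (replicate-mean) RPKMs per
    merged interval. WT RPKM of zero makes the ratio undefined; no pseudocount
    is applied and the record is marked unclassifiable.
    """
    wt = np.asarray(wt_rpkm, dtype=float)
    ko = np.asarray(ko_rpkm, dtype=float)
    if not (len(merged) == wt.size == ko.size):
        raise ValueError("merged intervals and RPKM vectors differ in length")
    if (wt < 0).any() or (ko < 0).any():
        raise ValueError("RPKM must be non-negative")
    rows = []
    for iv, w, k in zip(merged, wt, ko):
        if w == 0:
            ratio, cls = np.nan, UNCLASSIFIABLE
        else:
            ratio = k / w
            cls = classify_ratio(ratio, lower, upper)
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "wt_rpkm": w,
                "ko_rpkm": k,
                "ratio": ratio,
                "ubp_class": cls,
            }
        )
    return pd.DataFrame(rows)


class FeatureAnnotator:
    """Assigns promoter/genebody/intergenic labels and TE subfamily overlaps."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        genome: GenomeSpec,
        te: TEAnnotation | None = None,
        promoter_halfwidth: int = 3000,
        priority: tuple[str, str] = (PROMOTER, GENEBODY),
    ):
        genes = list(genes)
        if not genes:
            raise ValueError("gene set must be non-empty")
        promoters, bodies = [], []
        for g in genes:
            chrom_len = genome.length_of(g.chrom)
            s = max(0, g.tss - promoter_halfwidth)
            e = min(chrom_len, g.tss + promoter_halfwidth)
            if s < e:
                promoters.append(Interval(g.chrom, s, e))
            bodies.append(g.body)
        self.genome = genome
        self.priority = priority
        self._indexes = {
            PROMOTER: IntervalIndex(promoters, genome),
            GENEBODY: IntervalIndex(bodies, genome),
        }
        self._te = te
        if te is not None:
            self._te_indexes = {
                sf: IntervalIndex(te.intervals_of(subfamily=sf), genome)
                for sf in sorted(te.subfamilies)
            }
        else:
            self._te_indexes = {}

    def feature_of(self, iv: Interval) -> str:
        s, e = self.genome.to_absolute([iv])
        for label in self.priority:
            if int(self._indexes[label].coverage(s, e)[0]) > 0:
                return label
        return INTERGENIC

    def te_subfamilies_of(self, iv: Interval) -> list[str]:
        s, e = self.genome.to_absolute([iv])
        return [
            sf for sf, idx in self._te_indexes.items() if int(idx.coverage(s, e)[0]) > 0
        ]


def annotate_feature(
    interval: Interval,
    genes: Iterable[GeneModel],
    genome: GenomeSpec,
    te: TEAnnotation | None = None,
    promoter_halfwidth: int = 3000,
) -> tuple[str, list[str]]:
    """One-shot feature annotation of a single interval."""
    ann = FeatureAnnotator(genes, genome, te, promoter_halfwidth)
    return ann.feature_of(interval), ann.te_subfamilies_of(interval)


def annotate_ubp_table(ubps: pd.DataFrame, annotator: FeatureAnnotator) -> pd.DataFrame:
    """Add feature and te_subfamilies columns to a classify_ubps table."""
    features, te_lists = [], []
    for row in ubps.itertuples(index=False):
        iv = Interval(row.chrom, row.start, row.end)
        features.append(annotator.feature_of(iv))
        te_lists.append(",".join(annotator.te_subfamilies_of(iv)))
    out = ubps.copy()
    out["feature"] = features
    out["te_subfamilies"] = te_lists
    return out


def compare_class_distributions(
    primitive_counts: dict[str, int],
    enhanced_counts: dict[str, int],
) -> pd.DataFrame:
    """Per-category Fisher's exact test of primitive vs enhanced composition.

    For each category the 2x2 table is [in-category vs not] x [primitive vs
    enhanced]. P values are reported raw; apply BH downstream if desired.
    """
    if set(primitive_counts) != set(enhanced_counts):
        raise ValueError("category sets differ between classes")
    total_p = sum(primitive_counts.values())
    total_e = sum(enhanced_counts.values())
    rows = []
    for cat in sorted(primitive_counts):
        a, b = primitive_counts[cat], total_p - primitive_counts[cat]
        c, d = enhanced_counts[cat], total_e - enhanced_counts[cat]
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append({"category": cat, "odds_ratio": odds, "p": p})
    return pd.DataFrame(rows)
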