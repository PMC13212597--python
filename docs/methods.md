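# Methods

This note documents the models, conventions, default parameters and design
choices of ubptools, and what the synthetic-data tests do and do not show.

## Coordinates and interval algebra

All coordinates are 0-based, half-open (BED convention) internally;
RepeatMasker/GTF-style 1-based inclusive tables are converted on read.
`union_merge` merges overlapping *and bookended* intervals (end == next
start), matching reduce-style merging; "overlap" means ≥ 1 shared base
throughout, since no reciprocal-overlap fraction is part of any rule here.
`overlap_bp` is union overlap: bases covered by both merged sets, counted
once. A concatenated "absolute" coordinate system (chromosomes laid end to
end) backs the vectorized machinery; because no interval crosses a
chromosome boundary, sorting, merging and prefix-sum coverage queries become
one-dimensional array operations.

## Permutation TE enrichment

Null model: each query region is re-placed independently; a chromosome is
chosen with probability proportional to its number of feasible start
positions for that region's length, then the start is uniform among those
positions. Regions may change chromosome and may overlap each other (no
self-avoidance), mirroring the default behavior of the standard
shuffle tool this emulates. Placements overlapping the exclusion set
(blacklist) are rejected and redrawn, with a cap of 1000 retries per region
before a named error. Per permutation the union overlap between the shuffled
set and the merged TE intervals is recorded; the odds ratio is
observed / mean(permuted), and the empirical P is (k+1)/(N+1) with ties
("≥ observed") counted into k, so P ∈ [1/(N+1), 1] by construction. If the
permuted mean is zero the odds ratio is reported as +inf with a warning; the
empirical P remains valid. Default N = 10,000, overridable for desk-scale
runs. The TE universe is not blacklist-subtracted before the overlap
computation; only the placements avoid the blacklist.

Batch implementation: permutations are drawn in chunks; per chunk, row-wise
sorting plus a running maximum of interval ends reduces union overlap to
prefix-sum lookups into the TE coverage index, so a 1000-permutation test of
300 regions takes ~0.1 s on one core.

Calibration (recomputed by `scripts/acceptance.py` and the test suite): with
query sets drawn by the same placement law, the mean odds ratio over 50
replicates is 1 within ±0.05, and over 500 null runs Pr(p ≤ 0.05) stays
≤ 0.08 (the (k+1)/(N+1) form is conservatively super-uniform). The null
calibration runs use 100 regions and N = 199 permutations on a 1 Mb genome —
small enough to repeat 500 times routinely, large enough that the p-grid is
fine relative to the 0.05 threshold.

## Peak QC

ATAC-style retention requires, in this order of reporting: ≥ 1 bp overlap
with a replicate-2 peak; length strictly > 100 bp; mean replicate RPKM
strictly > 50; max/min replicate RPKM ratio strictly < 2. The combination
rules (mean for the RPKM gate, max/min for the fold gate) are symmetric in
the replicates; retained coordinates come from replicate 1 (configurable).
H3K9me3-style sets require overlap support in every replicate; UHRF1-style
sets additionally require treatment RPKM strictly above the Input. Blacklist
overlap of ≥ 1 bp excludes a peak anywhere. A top-AUC cut (e.g. the top 1%
of regions by area under the curve) is available as an optional
re-application for peak sets carrying AUC fields; peak calling itself is
upstream and out of scope. Each removed peak carries one failure reason (the
first failing rule), so reasons partition the removed set and counts are
conserved.

## UBP classes

WT and KO peak sets are union-merged; per merged interval, condition-level
RPKM is the replicate mean, and one ratio KO/WT is formed (replicates are
averaged before the ratio, not after). Boundaries follow the printed
definition: primitive [0.8, 1.2), enhanced [1.2, ∞). Ratios below 0.8 are
kept under the label *reduced* rather than silently dropped, and WT = 0
yields *unclassifiable* with no pseudocount — a pseudocount would move the
printed boundaries. Feature annotation assigns one primary label with
priority promoter > genebody > intergenic; the promoter is ±3 kb around the
strand-resolved TSS, the genebody spans TSS-TES, and intergenic is the
complement. Class-composition differences are tested per category with
Fisher's exact test on [in-category vs not] × [primitive vs enhanced];
P values are reported raw (BH available downstream), matching how such
per-category tests are usually printed.

## Allele split

Each read is profiled at the known SNP sites it covers: n_mat, n_pat, n_del
(deletion/N at a SNP site) and n_total (all covered SNP sites, including
those matching neither parental allele — they dilute the indicator, because
the denominator is "# SNP sites", not "# informative sites"). Rules in
order: n_del > 2 → excluded; n_total = 0 → unassigned; indicator
(n_mat − n_pat − n_del)/n_total > 0.5 → maternal; < −0.5 → paternal;
otherwise ambiguous. Both thresholds are strict, mirroring the wording for
the maternal side. Note an inherent asymmetry of this indicator: deletions
are subtracted from the numerator, so allele exchange is not an odd
transformation when n_del > 0 — a deletion-bearing maternal call always maps
to paternal under a label swap, but not conversely. The tests assert exactly
this (full antisymmetry only at n_del = 0). The same algorithm is applied
uniformly; the short-read-specific splitter it derives from is not
re-implemented.

## ZGA expression

Minor rule baseline: max(FGO, MII) + 0.5 FPKM pseudocount (oocyte expression
can be zero); the ≥ 3× rise is evaluated against this oocyte baseline for
both the 1-cell and early 2-cell stages, alongside the absolute FPKM > 5
gates. Major rule baseline: the FGO/MII mean, with gate mean > 5 and a
strictly more-than-5× late-2-cell rise. Minor is checked first. Both
baselines and folds are configurable. Downregulation: log₂FC from
pseudocounted condition means, Welch's t on log₂(FPKM + 0.5) per gene, BH
across tested genes (genes with zero FPKM everywhere are excluded from
testing, shrinking the BH denominator), flag iff log₂FC < −0.5 and
FDR < 0.05. The paper-style rescue arithmetic (percent of ZGA genes down in
model A; percent of those not down in model B) is plain set arithmetic.

## Methylation

Context calling is a pure function of the reference trinucleotide: WCG iff
(A|T)CG, GCH iff GC(A|T|C), everything else (notably GCG, ambiguous between
the two assays) is "other". Minus-strand cytosines are evaluated on the
reverse complement, per standard bisulfite convention; WCG sites are counted
per site per strand (no CpG symmetrization). Region and feature levels are
pooled counts n_meth/n_total; aggregation across single embryos concatenates
calls, so pooled levels are coverage-weighted by construction. 1-kb tiles
partition each chromosome; tiles with < 3 covered sites (default) are
excluded; the categorical label uses configurable breakpoints (default
quintiles 0.2/0.4/0.6/0.8 — the published figure's breakpoints are not
printed, so none are asserted anywhere).

## Motif backgrounds

Each selected peak contributes a 200-bp window centered on its signal
maximum (leftmost on ties); windows running past a chromosome end are
shifted back inside and flagged. Background sampling center-trims pool
regions to 200 bp, computes GC, and matches the target histogram exactly per
0.05-wide GC bin, without replacement; an under-populated bin is a named
error, not a silent approximation. Bin-exact matching pins the target and
background GC CDFs together at every bin boundary; the KS distance between
them is therefore bounded by the largest single bin's share of the targets
(not by the bin width). Hit filtering keeps hits with score > 2 (strict),
E-value < 10⁻¹⁰ (strict) and gene expression at or above the median of the
expressed (non-zero) genes in the supplied table — ties at the cutoff are
retained, and the ranking stage/table is caller-supplied. Motif scanning
itself is consumed from a generic hits table, never re-implemented.

## Synthetic data

One global seed fans out to per-generator child streams keyed by
(seed, stream name) via SeedSequence, so adding a generator never perturbs
another's draws; everything is bit-reproducible. Defaults emulate the study
conditions at desk scale: peak lengths log-normal (median 600 bp, σ_log 0.5)
truncated to [100 bp, 10 kb], the retained-peak regime; replicate RPKM noise
multiplicative log-normal with mean 1 and CV 0.1; SNPs biallelic with fixed
maternal/paternal bases (an N-masked two-strain cross), density 1-2 per kb;
planted KO-enhanced peaks at 2× WT signal; planted minor/major ZGA genes
satisfy their rules with margin (oocyte FPKM < 2 and embryonic stages in
[8, 50] for minor; oocyte [6, 15] with a 6-10× late rise for major); planted
knockout downregulation 4-fold with CV 0.05 over 4 replicates; methylation
calls Bernoulli at the region's true level at sites scanned from the actual
generated sequence. The generators do *not* model alignment error, mapping
bias, fragment-length structure, bisulfite conversion failure, copy-number
variation or realistic TE sequence divergence — so passing tests demonstrate
the correctness and calibration of the downstream arithmetic, not robustness
to those upstream artifacts.

## Numerical and scale choices

Analyses in `analysis/` run on a 2 × 400 kb genome with ~150-200 peaks,
500 reads, 200 genes and 12,000 methylation calls; the calibration script
uses a 10 Mb genome. These sizes were chosen so every quantity that should
be recovered (planted enrichment, planted classes, null calibration) is
resolved with comfortable statistical margin while any stage reruns in
seconds. Degenerate inputs are errors, not silent defaults: zero-variance
correlation, zero pooled SD, zero library size, empty region sets, WT = 0
ratios, reads covering no SNP. Empirical-P ties count toward k;
deterministic leftmost tie-breaks are used for summit selection.

## Known limitations

- The enrichment shuffle has no same-chromosome or GC-aware variant; GC
  control belongs to the motif background module.
- `qc_atac` takes replicate-1 coordinates for retained peaks rather than
  re-merging the replicate pair.
- The per-category Fisher tests are marginal (one test per category), not a
  joint composition test.
- Real-study headline counts (peak numbers, ZGA downregulation percentages)
  depend on the deposited sequencing data and are outside what synthetic
  calibration can or should reproduce.
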