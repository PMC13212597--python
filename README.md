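# ubptools

Downstream computations for mouse early-embryo multi-omics studies of
UHRF1 chromatin binding and zygotic genome activation (ZGA), packaged as a
tested, reusable pipeline that runs end-to-end on synthetic data with
planted ground truth.

The package is aimed at computational biologists who need the bespoke
"methods section" arithmetic of such studies as importable, verifiable code
rather than one-off scripts:

- **Peak QC** — replicate-concordance retention filters for ATAC / CUT&Tag
  style peak sets: support in both (or all) replicates, length > 100 bp,
  mean replicate RPKM > 50, < 2-fold RPKM difference between replicates,
  treatment > Input, blacklist exclusion.
- **UHRF1-binding-peak (UBP) classes** — WT and maternal-knockout peak sets
  merged into one universe and classified by the KO-to-WT mean-RPKM ratio:
  *primitive* (0.8 ≤ ratio < 1.2), *enhanced* (ratio ≥ 1.2), plus *reduced*
  (< 0.8) and *unclassifiable* (WT RPKM = 0); promoter (±3 kb of the
  strand-aware TSS) / genebody / intergenic annotation and per-category
  Fisher tests of class composition.
- **Permutation TE enrichment** — the core statistic. For a region set *R*
  and a merged transposable-element (TE) interval set *T*, the observed
  base-pair overlap is compared against N random re-placements of *R* that
  preserve region number and lengths and avoid a blacklist:

      odds ratio = observed overlap / mean permuted overlap
      empirical P = (k + 1) / (N + 1),  k = #{permutations ≥ observed}

  with N = 10,000 by default, so the attainable floor is P ≈ 1 × 10⁻⁴.
- **Allele split** — per-read assignment in a C57BL/6J × PWK/PhJ cross
  aligned to an N-masked genome, via the indicator
  (#maternal − #paternal − #N-deletion SNP sites) / #SNP sites:
  maternal if > 0.5, paternal if < −0.5, excluded above 2 N-deletions.
- **ZGA expression rules** — minor ZGA (oocyte FPKM < 5; 1-cell and early
  2-cell FPKM > 5 with ≥ 3× rise) and major ZGA (oocyte FPKM > 5; late
  2-cell > 5× oocyte); knockout downregulation at log₂FC < −0.5 and
  BH-adjusted P < 0.05 (Welch's t on log₂(FPKM + 0.5)).
- **WCG/GCH methylation summaries** — cytosine-context calling (WCG = A/T
  before CG, reporting endogenous CpG methylation; GCH = GpC followed by
  A/T/C, reporting GpC-methyltransferase accessibility; GCG excluded),
  region and 1-kb-tile levels, single-embryo aggregation by pooled counts.
- **Motif backgrounds** — 200-bp summit windows over selected TE subtypes
  and a background matched in number, length and GC content (exact per
  0.05-wide GC bin, sampled without replacement), plus post-hoc filtering of
  motif-enrichment hits (expression in the top 50%, score > 2, E < 10⁻¹⁰).
- **Synthetic data** — seeded generators for every input above with planted
  truth (TE-enriched peaks, KO-enhanced peaks, reads of known parental
  origin, minor/major ZGA genes, region methylation levels), so each stage
  is testable without any download.

## Worked example

The repository is organised as an analysis: numbered drivers under
`analysis/` run each stage on the synthetic study and write tables under
`results/` (bulky intermediates go to `scratch/`).

```bash
python analysis/01_simulate_inputs.py   # genome, TEs, peaks, SNPs, FPKM, methylation
python analysis/02_peak_qc.py
python analysis/03_classify_ubps.py
python analysis/04_te_enrichment.py
```

With the default seed, 150 peaks are simulated, half of them planted inside
the LINE subfamily L1Md_A. Step 04 prints:

```
--- subclass (2000 permutations) ---
te_label  observed_overlap  perm_mean  odds_ratio    k        p  n_perm
    LINE             44408  14648.657    3.031541    0 0.000500    2000
     LTR             18635  27858.581    0.668914 2000 1.000000    2000
    SINE              1071   2735.326    0.391544 1994 0.997001    2000
```

The planted LINE enrichment is recovered with an odds ratio of ~3 at the
empirical-P floor 1/(N+1) = 5 × 10⁻⁴ (k = 0: no random placement reached the
observed overlap), while the unenriched LTR and SINE subclasses sit at or
below an odds ratio of 1 with non-significant P. Step 03 reports that 100%
of the planted 2× KO-enhanced peaks are labeled *enhanced*, and steps 05-08
cover allele splitting (99.8% of assigned reads match the planted origin),
ZGA classification (all planted minor/major genes recovered; all 40 planted
4-fold-down genes called, zero false positives), methylation summaries
(observed region levels 0.7995 / 0.2000 / 0.3525 against planted 0.8 / 0.2 /
0.35) and GC-matched motif backgrounds.

The same stages are available as a CLI (`ubp simulate`, `ubp qc-atac`,
`ubp classify`, `ubp enrich`, `ubp split`, `ubp zga`, `ubp meth`,
`ubp motif-prep`, `ubp motif-filter`, `ubp demo`) and as one orchestrated
run (`ubptools.pipeline.run_pipeline`).

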