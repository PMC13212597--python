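"""Config-driven orchestration of the full synthetic pipeline.

Every printed analysis threshold is a configurable default here; the demo
exercises each stage on a small synthetic genome and writes TSV outputs plus
a JSON manifest with content hashes, so re-runs are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import simulate as sim
from .allele_split import SnpTable, split_reads
from .genome import Blacklist, Interval
from .io_tables import write_bed, write_repeatmasker_table
from .meth_summary import feature_meth, tile_levels
from .motif_background import (
    filter_motif_hits,
    intersect_ubps_with_subtypes,
    sample_matched_background,
    summit_window,
)
from .peak_qc import apply_blacklist, qc_atac
from .te_enrichment import enrichment_table
from .ubp_classes import FeatureAnnotator, annotate_ubp_table, classify_ubps
from .zga_expr import call_downregulated, classify_zga_table, fraction_recovered


@dataclass
class RunConfig:
    """All thresholds of the pipeline, defaulting to the published values."""

    seed: int = 1
    out_dir: str = "demo_out"
    # peak QC
    min_peak_length: int = 100
    min_rpkm: float = 50.0
    max_replicate_fold: float = 2.0
    # UBP classes
    ratio_lower: float = 0.8
    ratio_upper: float = 1.2
    promoter_halfwidth: int = 3000
    # allele split
    indicator_cut: float = 0.5
    max_n_del: int = 2
    # ZGA rules
    fpkm_gate: float = 5.0
    minor_fold: float = 3.0
    major_fold: float = 5.0
    lfc_cut: float = -0.5
    alpha: float = 0.05
    # enrichment
    n_perm: int = 10_000
    # motif
    window: int = 200
    min_score: float = 2.0
    max_e: float = 1e-10
    top_fraction: float = 0.5

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_demo(config: RunConfig) -> dict:
    """End-to-end synthetic run of every stage; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {"seed": seed, "config": config.to_dict(), "outputs": {}}

    # --- synthetic inputs -------------------------------------------------
    genome = sim.gen_genome(sim.GenomeParams(n_chrom=2, chrom_length=400_000), seed)
    te = sim.gen_te_annotation(
        genome.spec,
        {
            "L1Md_A": sim.TESubfamilySpec("LINE", 120, 900),
            "IAPEz-int": sim.TESubfamilySpec("LTR", 60, 1200),
            "RLTR10": sim.TESubfamilySpec("LTR", 400, 350),
            "B1_Mm": sim.TESubfamilySpec("SINE", 100, 200),
        },
        seed,
    )
    blacklist = Blacklist(
        [Interval("chr1", 50_000, 55_000), Interval("chr2", 300_000, 305_000)]
    )
    peaks, peak_truth = sim.gen_peaks(
        genome.spec,
        sim.PeakParams(count=150, enrichment_fraction=0.5, target_subfamily="L1Md_A",
                       noise_cv=0.1),
        te=te,
        seed=seed,
        blacklist=blacklist,
    )
    write_repeatmasker_table(out / "te_annotation.tsv", te)
    write_bed(out / "peaks.bed", peaks.intervals, names=[p.id for p in peaks])

    # --- peak QC ----------------------------------------------------------
    kept, qc_report = qc_atac(
        peaks, peaks, rpkm_samples=("rep1", "rep2"),
        min_len=config.min_peak_length, min_rpkm=config.min_rpkm,
        max_fold=config.max_replicate_fold,
    )
    kept, bl_report = apply_blacklist(kept, blacklist)
    qc_report.table.to_csv(out / "qc_report.tsv", sep="\t", index=False)

    # --- UBP classification ----------------------------------------------
    wtko = sim.gen_wt_ko_peaks(genome.spec, count=200, enhanced_fraction=0.3, seed=seed)
    merged = [Interval(r.chrom, r.start, r.end) for r in wtko.itertuples(index=False)]
    ubps = classify_ubps(merged, wtko["wt_rpkm"], wtko["ko_rpkm"],
                         lower=config.ratio_lower, upper=config.ratio_upper)
    genes = sim.gen_genes(genome.spec, count=30, mean_length=15_000, seed=seed)
    annotator = FeatureAnnotator(genes, genome.spec, te,
                                 promoter_halfwidth=config.promoter_halfwidth)
    ubps = annotate_ubp_table(ubps, annotator)
    ubps["true_enhanced"] = wtko["true_enhanced"].to_numpy()
    ubps.to_csv(out / "ubp_classes.tsv", sep="\t", index=False)

    # --- TE enrichment ----------------------------------------------------
    enr = enrichment_table(
        kept.intervals, te, genome.spec, group_by="subclass",
        exclude=blacklist, n_perm=config.n_perm, seed=seed,
    )
    enr.to_csv(out / "te_enrichment.tsv", sep="\t", index=False)

    # --- allele split -----------------------------------------------------
    snps = sim.gen_snp_table(genome, snp_density=1.0, seed=seed)
    observations, read_truth = sim.gen_reads_with_snps(
        genome, snps, sim.ReadParams(count=400, length=4000), maternal_fraction=0.5,
        seed=seed,
    )
    calls, summary = split_reads(observations, SnpTable(snps),
                                 indicator_cut=config.indicator_cut,
                                 max_n_del=config.max_n_del,
                                 read_ids=read_truth["read_id"])
    calls.to_csv(out / "allele_calls.tsv", sep="\t", index=False)

    # --- ZGA expression ---------------------------------------------------
    stage, wt, ko, expr_truth = sim.gen_expression(sim.ExprParams(), seed)
    zga = classify_zga_table(stage, fpkm_gate=config.fpkm_gate,
                             minor_fold=config.minor_fold, major_fold=config.major_fold)
    de = call_downregulated(wt, ko, lfc_cut=config.lfc_cut, alpha=config.alpha)
    _, wt2, ko2, _ = sim.gen_expression(
        sim.ExprParams(n_down=0), seed + 1
    )
    de_rescue = call_downregulated(wt2, ko2, lfc_cut=config.lfc_cut, alpha=config.alpha)
    zga_set = set(zga.loc[zga["zga_class"] != "none", "gene_id"])
    recovery = fraction_recovered(
        zga_set,
        set(de.index[de["downregulated"]]),
        set(de_rescue.index[de_rescue["downregulated"]]),
    )
    zga.to_csv(out / "zga_classes.tsv", sep="\t", index=False)
    de.to_csv(out / "de_results.tsv", sep="\t")

    # --- methylation ------------------------------------------------------
    meth_specs = [
        sim.MethRegionSpec(Interval("chr1", 100_000, 140_000), "WCG", 0.8, 4000),
        sim.MethRegionSpec(Interval("chr1", 200_000, 240_000), "WCG", 0.2, 4000),
        sim.MethRegionSpec(Interval("chr2", 100_000, 140_000), "GCH", 0.35, 4000),
    ]
    meth_calls, meth_truth = sim.gen_methylation(genome, meth_specs, seed)
    tiles = tile_levels(meth_calls, genome.spec, "WCG", tile=1000, min_sites=3)
    features = {"L1Md_A": te.intervals_of(subfamily="L1Md_A"),
                "IAPEz-int": te.intervals_of(subfamily="IAPEz-int")}
    fmeth = feature_meth(meth_calls, features, "WCG")
    tiles.to_csv(out / "meth_tiles.tsv", sep="\t", index=False)
    fmeth.to_csv(out / "feature_meth.tsv", sep="\t", index=False)

    # --- motif background -------------------------------------------------
    rng = sim.child_rng(seed, "motif_demo")
    ltr_ubps = intersect_ubps_with_subtypes(kept, te, ["IAPEz-int"], genome.spec)
    targets = []
    for i, iv in enumerate(ltr_ubps):
        signal = rng.random(iv.length)
        targets.append(
            summit_window(iv, signal, genome.spec, genome.sequences,
                          source_id=f"ubp_{i}", width=config.window)
        )
    pool = te.intervals_of(subfamily="RLTR10")
    background = (
        sample_matched_background(targets, pool, genome.spec, genome.sequences,
                                  seed=rng, width=config.window)
        if targets else []
    )
    hits = pd.DataFrame(
        {
            "motif": [f"M{i}" for i in range(6)],
            "gene": [f"gene_{i:05d}" for i in range(6)],
            "score": [3.0, 1.5, 2.5, 4.0, 2.1, 0.5],
            "e_value": [1e-12, 1e-12, 1e-5, 1e-20, 1e-15, 0.5],
        }
    )
    expression = {f"gene_{i:05d}": float(v) for i, v in enumerate(
        sim.child_rng(seed, "motif_expr").lognormal(2, 1, 6))}
    retained_hits = filter_motif_hits(hits, expression, min_score=config.min_score,
                                      max_e=config.max_e,
                                      top_fraction=config.top_fraction)
    retained_hits.to_csv(out / "motif_hits_filtered.tsv", sep="\t", index=False)

    # --- manifest ---------------------------------------------------------
    summary_block = {
        "n_peaks_in": len(peaks),
        "n_peaks_qc": qc_report.n_retained,
        "n_peaks_final": len(kept),
        "ubp_class_counts": ubps["ubp_class"].value_counts().to_dict(),
        "enrichment": {
            row["te_label"]: {"odds_ratio": row["odds_ratio"], "p": row["p"]}
            for _, row in enr.iterrows()
        },
        "allele_summary": summary,
        "zga_counts": zga["zga_class"].value_counts().to_dict(),
        "n_downregulated": int(de["downregulated"].sum()),
        "zga_recovery": recovery,
        "n_meth_tiles": len(tiles),
        "n_motif_targets": len(targets),
        "n_motif_background": len(background),
        "n_motif_hits_retained": len(retained_hits),
    }
    manifest["summary"] = summary_block
    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed")):
        manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_pipeline(config: RunConfig) -> dict:
    """Validate the config and run the synthetic pipeline end to end."""
    if config.n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < config.alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return run_demo(config)
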