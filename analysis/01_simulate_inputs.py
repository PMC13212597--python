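"""Generate the synthetic study inputs with planted truth.

Writes the genome, TE annotation, blacklist, peaks (with replicate RPKM),
SNPs, long reads, expression matrices and methylation calls that the later
scripts consume. Everything is seeded, so any script can also regenerate its
inputs in memory.
"""

import pandas as pd

import params
from params import RESULTS, SCRATCH, SEED

from ubptools import simulate as sim
from ubptools.genome import Interval
from ubptools.io_tables import write_bed, write_fasta, write_repeatmasker_table, write_snp_table


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    genome = params.genome()
    with open(SCRATCH / "chrom.sizes", "w") as fh:
        for name, length in zip(genome.spec.chrom_names, genome.spec.chrom_lengths):
            fh.write(f"{name}\t{int(length)}\n")
    write_fasta(SCRATCH / "genome.fa", genome.sequences)

    te = params.te_annotation(genome.spec)
    write_repeatmasker_table(SCRATCH / "te_annotation.tsv", te)
    bl = params.blacklist()
    write_bed(SCRATCH / "blacklist.bed", list(bl))

    peaks, peak_truth = sim.gen_peaks(
        genome.spec,
        sim.PeakParams(count=params.N_PEAKS,
                       enrichment_fraction=params.PEAK_ENRICHMENT_FRACTION,
                       target_subfamily=params.PEAK_TARGET, noise_cv=0.1),
        te=te, seed=SEED, blacklist=bl,
    )
    write_bed(SCRATCH / "peaks.bed", peaks.intervals, names=[p.id for p in peaks])
    pd.DataFrame(
        {"peak_id": [p.id for p in peaks],
         "rep1": [p.rpkm_by_sample["rep1"] for p in peaks],
         "rep2": [p.rpkm_by_sample["rep2"] for p in peaks]}
    ).to_csv(SCRATCH / "peak_rpkm.tsv", sep="\t", index=False)
    peak_truth.to_csv(SCRATCH / "peak_truth.tsv", sep="\t", index=False)

    wtko = sim.gen_wt_ko_peaks(genome.spec, count=200, enhanced_fraction=0.3,
                               ko_factor=2.0, noise_cv=0.1, seed=SEED)
    wtko.to_csv(SCRATCH / "wtko_peaks.tsv", sep="\t", index=False)

    snps = sim.gen_snp_table(genome, snp_density=1.0, seed=SEED)
    write_snp_table(SCRATCH / "snps.tsv", snps)
    obs, read_truth = sim.gen_reads_with_snps(
        genome, snps, sim.ReadParams(count=500, length=4000,
                                     n_deletion_rate=0.02, error_rate=0.01),
        maternal_fraction=0.5, seed=SEED,
    )
    obs.to_csv(SCRATCH / "read_observations.tsv", sep="\t", index=False)
    read_truth.to_csv(SCRATCH / "read_truth.tsv", sep="\t", index=False)

    stage, wt, ko, expr_truth = sim.gen_expression(sim.ExprParams(), SEED)
    stage.to_csv(SCRATCH / "stage_fpkm.tsv", sep="\t", index=False)
    wt.to_csv(SCRATCH / "wt_fpkm.tsv", sep="\t")
    ko.to_csv(SCRATCH / "ko_fpkm.tsv", sep="\t")
    expr_truth.to_csv(SCRATCH / "expr_truth.tsv", sep="\t", index=False)
    # a "rescue" model: same WT baseline, no planted downregulation
    _, wt2, ko2, _ = sim.gen_expression(sim.ExprParams(n_down=0), SEED + 1)
    wt2.to_csv(SCRATCH / "wt2_fpkm.tsv", sep="\t")
    ko2.to_csv(SCRATCH / "ko2_fpkm.tsv", sep="\t")

    meth_specs = [
        sim.MethRegionSpec(Interval("chr1", 100_000, 140_000), "WCG", 0.8, 4000),
        sim.MethRegionSpec(Interval("chr1", 200_000, 240_000), "WCG", 0.2, 4000),
        sim.MethRegionSpec(Interval("chr2", 100_000, 140_000), "GCH", 0.35, 4000),
    ]
    calls, meth_truth = sim.gen_methylation(genome, meth_specs, SEED)
    calls.to_csv(SCRATCH / "meth_calls.tsv", sep="\t", index=False)
    meth_truth.to_csv(SCRATCH / "meth_truth.tsv", sep="\t", index=False)

    print(f"synthetic inputs written to {SCRATCH}")
    print(f"  {params.N_PEAKS} peaks ({params.PEAK_ENRICHMENT_FRACTION:.0%} planted "
          f"in {params.PEAK_TARGET}), {len(snps)} SNPs, {len(obs)} read-site "
          f"observations, {len(stage)} genes, {len(calls)} methylation calls")


if __name__ == "__main__":
    main()
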