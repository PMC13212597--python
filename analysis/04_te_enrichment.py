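"""Permutation TE-enrichment of the QC-retained peaks.

Half of the simulated peaks were planted inside L1Md_A (a LINE subfamily), so
the LINE subclass should come out enriched (odds ratio > 1, empirical P at
the (k+1)/(N+1) floor) while LTR/SINE should not.
"""

import params
from params import N_PERM, RESULTS, SCRATCH, SEED

from ubptools.io_tables import read_bed
from ubptools.te_enrichment import enrichment_table


def main() -> None:
    genome = params.genome()
    te = params.te_annotation(genome.spec)
    regions = read_bed(SCRATCH / "peaks_qc.bed", genome.spec)

    for group in ("subclass", "subfamily"):
        table = enrichment_table(
            regions, te, genome.spec, group_by=group,
            exclude=params.blacklist(), n_perm=N_PERM, seed=SEED,
        )
        table.to_csv(RESULTS / f"te_enrichment_{group}.tsv", sep="\t", index=False)
        print(f"--- {group} ({N_PERM} permutations) ---")
        print(table.to_string(index=False))


if __name__ == "__main__":
    main()
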