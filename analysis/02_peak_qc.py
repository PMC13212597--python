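"""Apply the peak-retention filters to the simulated replicate peaks.

Filters: replicate support, length > 100 bp, mean replicate RPKM > 50,
< 2-fold RPKM difference between replicates, blacklist exclusion. Writes the
retained peak BED and a per-filter attrition summary.
"""

import pandas as pd

import params
from params import RESULTS, SCRATCH

from ubptools.genome import Peak, PeakSet
from ubptools.io_tables import read_bed, write_bed
from ubptools.peak_qc import apply_blacklist, qc_atac


def main() -> None:
    genome = params.genome()
    intervals = read_bed(SCRATCH / "peaks.bed", genome.spec)
    rpkm = pd.read_csv(SCRATCH / "peak_rpkm.tsv", sep="\t").set_index("peak_id")
    peaks = PeakSet(
        [Peak(iv, pid, {"rep1": row.rep1, "rep2": row.rep2})
         for iv, (pid, row) in zip(intervals, rpkm.iterrows())],
        genome.spec,
    )

    kept, report = qc_atac(peaks, peaks, rpkm_samples=("rep1", "rep2"))
    kept, bl_report = apply_blacklist(kept, params.blacklist())

    write_bed(SCRATCH / "peaks_qc.bed", kept.intervals, names=[p.id for p in kept])
    summary = pd.DataFrame(
        [{"filter": "input", "n": report.n_in}]
        + [{"filter": reason, "n": n} for reason, n in report.counts_by_reason().items()]
        + [{"filter": "blacklist", "n": sum(bl_report.counts_by_reason().values())},
           {"filter": "retained", "n": len(kept)}]
    )
    summary.to_csv(RESULTS / "peak_qc_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
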