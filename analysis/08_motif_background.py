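"""Build motif-analysis inputs: summit windows and a GC-matched background.

Selects QC-retained peaks overlapping the LTR subfamily IAPEz-int, extracts
200-bp summit windows, samples a background from the other LTR subfamily
(RLTR10) matched in number, length and GC bins, writes both as FASTA, and
filters a synthetic motif-hit table on expression rank, score and E-value.
"""

import numpy as np
import pandas as pd

import params
from params import RESULTS, SCRATCH, SEED

from ubptools import simulate as sim
from ubptools.io_tables import read_bed, write_fasta
from ubptools.motif_background import (
    filter_motif_hits,
    intersect_ubps_with_subtypes,
    sample_matched_background,
    summit_window,
)


def main() -> None:
    genome = params.genome()
    te = params.te_annotation(genome.spec)
    peaks = read_bed(SCRATCH / "peaks_qc.bed", genome.spec)
    rng = sim.child_rng(SEED, "motif_analysis")

    ltr_peaks = intersect_ubps_with_subtypes(peaks, te, ["IAPEz-int"], genome.spec)
    targets = [
        summit_window(iv, rng.random(iv.length), genome.spec, genome.sequences,
                      source_id=f"ubp_{i}")
        for i, iv in enumerate(ltr_peaks)
    ]
    pool = te.intervals_of(subfamily="RLTR10")
    background = sample_matched_background(targets, pool, genome.spec,
                                           genome.sequences, seed=rng)
    write_fasta(SCRATCH / "motif_targets.fa",
                {f"{t.source_id}|{t.window.chrom}:{t.window.start}-{t.window.end}":
                 t.sequence for t in targets})
    write_fasta(SCRATCH / "motif_background.fa",
                {f"{b.source_id}|{b.window.chrom}:{b.window.start}-{b.window.end}":
                 b.sequence for b in background})
    gc_t = np.array([t.gc for t in targets])
    gc_b = np.array([b.gc for b in background])
    print(f"{len(targets)} target windows (GC {gc_t.mean():.3f}), "
          f"{len(background)} background (GC {gc_b.mean():.3f})")

    # synthetic scanner output: half the motifs pass the printed cuts
    n = 20
    hits = pd.DataFrame({
        "motif": [f"M{i:02d}" for i in range(n)],
        "gene": [f"tf_{i:02d}" for i in range(n)],
        "score": rng.uniform(0.5, 5.0, n),
        "e_value": 10.0 ** rng.uniform(-20, -2, n),
    })
    expression = {f"tf_{i:02d}": float(v)
                  for i, v in enumerate(rng.lognormal(2, 1, n))}
    retained = filter_motif_hits(hits, expression)
    retained.to_csv(RESULTS / "motif_hits_filtered.tsv", sep="\t", index=False)
    print(f"motif hits retained: {len(retained)}/{n} "
          "(top-50% expression, score > 2, E < 1e-10)")


if __name__ == "__main__":
    main()
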