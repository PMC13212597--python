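"""Summarize the simulated WCG/GCH calls: regions, 1-kb tiles, TE features.

Checks the recovered region levels against the planted truth, bins 1-kb
tiles into categorical methylation classes, and computes per-TE-subfamily
levels the way feature-level methylation tables are built.
"""

import pandas as pd

import params
from params import RESULTS, SCRATCH

from ubptools.genome import Interval
from ubptools.io_tables import read_meth_table
from ubptools.meth_summary import feature_meth, region_level, tile_levels


def main() -> None:
    genome = params.genome()
    calls = read_meth_table(SCRATCH / "meth_calls.tsv")
    truth = pd.read_csv(SCRATCH / "meth_truth.tsv", sep="\t")

    rows = []
    for r in truth.itertuples(index=False):
        lev = region_level(calls, Interval(r.chrom, r.start, r.end), r.context)
        rows.append({"chrom": r.chrom, "start": r.start, "end": r.end,
                     "context": r.context, "true_level": r.true_level,
                     "observed_level": lev.level, "n_calls": lev.n_total})
    regions = pd.DataFrame(rows)
    regions.to_csv(RESULTS / "meth_regions.tsv", sep="\t", index=False)
    print(regions.to_string(index=False))

    tiles = tile_levels(calls, genome.spec, "WCG", tile=1000, min_sites=3)
    tiles.to_csv(RESULTS / "meth_tiles_wcg.tsv", sep="\t", index=False)
    print("\n1-kb WCG tile categories:")
    print((tiles["category"].value_counts(normalize=True) * 100)
          .round(1).to_string())

    te = params.te_annotation(genome.spec)
    features = {sf: te.intervals_of(subfamily=sf) for sf in sorted(te.subfamilies)}
    fmeth = feature_meth(calls, features, "WCG")
    fmeth.to_csv(RESULTS / "meth_te_features.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
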