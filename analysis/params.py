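"""Shared settings of the synthetic study driven by the numbered scripts.

Bulky intermediates (sequences, per-site/per-read tables) go to scratch/;
small summary tables go to results/.
"""

from pathlib import Path

SEED = 1

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "synthetic_inputs"
RESULTS = ROOT / "results"

GENOME_CHROMS = 2
GENOME_LENGTH = 400_000

TE_SPEC = {
    # subfamily: (subclass, count, mean length)
    "L1Md_A": ("LINE", 120, 900),
    "IAPEz-int": ("LTR", 60, 1200),
    "RLTR10": ("LTR", 400, 350),
    "B1_Mm": ("SINE", 100, 200),
}

BLACKLIST = [("chr1", 50_000, 55_000), ("chr2", 300_000, 305_000)]

N_PEAKS = 150
PEAK_ENRICHMENT_FRACTION = 0.5
PEAK_TARGET = "L1Md_A"

N_PERM = 2000


def te_annotation(genome_spec):
    from ubptools import simulate as sim

    return sim.gen_te_annotation(
        genome_spec,
        {name: sim.TESubfamilySpec(sc, n, ml) for name, (sc, n, ml) in TE_SPEC.items()},
        SEED,
    )


def blacklist():
    from ubptools.genome import Blacklist, Interval

    return Blacklist([Interval(c, s, e) for c, s, e in BLACKLIST])


def genome():
    from ubptools import simulate as sim

    return sim.gen_genome(sim.GenomeParams(GENOME_CHROMS, GENOME_LENGTH), SEED)
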