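import numpy as np
import pytest

from ubptools.genome import GenomeSpec, Interval


@pytest.fixture
def genome() -> GenomeSpec:
    return GenomeSpec(["chr1", "chr2"], [10_000, 8_000])


def random_intervals(rng: np.random.Generator, genome: GenomeSpec, n: int) -> list[Interval]:
    """Uniform random valid intervals on a genome (shared test helper)."""
    out = []
    for _ in range(n):
        ci = int(rng.integers(0, len(genome)))
        chrom = genome.chrom_names[ci]
        length = int(rng.integers(1, 500))
        length = min(length, genome.length_of(chrom))
        start = int(rng.integers(0, genome.length_of(chrom) - length + 1))
        out.append(Interval(chrom, start, start + length))
    return out


def base_set(intervals, genome: GenomeSpec) -> set[tuple[str, int]]:
    """Per-base membership oracle representation of an interval set."""
    bases = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            bases.add((iv.chrom, pos))
    return bases
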