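"""Interval algebra and shared statistics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ubptools.genome import GenomeSpec, Interval, IntervalIndex, overlap_bp, union_merge
from ubptools.stats import cohens_d, fisher_exact_2x2, pearson_on_bins, rpkm

from conftest import base_set, random_intervals


class TestInterval:
    def test_valid(self):
        iv = Interval("chr1", 0, 100)
        assert iv.length == 100 and iv.strand == "."

    @pytest.mark.parametrize("start,end", [(-1, 10), (10, 10), (20, 10)])
    def test_invalid_coordinates(self, start, end):
        with pytest.raises(ValueError):
            Interval("chr1", start, end)

    def test_genome_bounds(self, genome):
        genome.validate_interval(Interval("chr1", 0, 10_000))
        with pytest.raises(ValueError):
            genome.validate_interval(Interval("chr1", 0, 10_001))
        with pytest.raises(ValueError):
            genome.validate_interval(Interval("chrX", 0, 10))

    def test_genome_spec_invariants(self):
        with pytest.raises(ValueError):
            GenomeSpec(["a", "a"], [10, 10])
        with pytest.raises(ValueError):
            GenomeSpec(["a"], [0])


class TestUnionMerge:
    def test_disjoint_unchanged(self):
        ivs = [Interval("chr1", 0, 10), Interval("chr1", 20, 30)]
        assert union_merge(ivs) == ivs

    def test_overlapping_merged(self):
        out = union_merge([Interval("chr1", 0, 10), Interval("chr1", 5, 15)])
        assert out == [Interval("chr1", 0, 15)]

    def test_bookended_merged(self):
        out = union_merge([Interval("chr1", 0, 10), Interval("chr1", 10, 20)])
        assert out == [Interval("chr1", 0, 20)]

    def test_random_cases_match_base_oracle(self, genome):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ivs = random_intervals(rng, genome, int(rng.integers(1, 30)))
            merged = union_merge(ivs)
            # idempotent
            assert union_merge(merged) == merged
            # pairwise disjoint and sorted within chromosomes
            for a, b in zip(merged, merged[1:]):
                if a.chrom == b.chrom:
                    assert a.end < b.start
            # base union preserved
            assert base_set(merged, genome) == base_set(ivs, genome)


class TestOverlapBp:
    def test_identity(self):
        ivs = [Interval("chr1", 0, 100), Interval("chr2", 5, 25)]
        assert overlap_bp(ivs, ivs) == 120

    def test_disjoint(self):
        assert overlap_bp([Interval("chr1", 0, 10)], [Interval("chr1", 50, 60)]) == 0

    def test_example_per_base(self):
        a = [Interval("chr1", 0, 100)]
        b = [Interval("chr1", 50, 150), Interval("chr1", 90, 120)]
        expected = len(base_set(a, None) & base_set(b, None))
        assert overlap_bp(a, b) == expected == 50

    def test_random_cases_match_base_oracle(self):
        genome = GenomeSpec(["c1", "c2"], [5_000, 5_000])
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            a = random_intervals(rng, genome, int(rng.integers(1, 20)))
            b = random_intervals(rng, genome, int(rng.integers(1, 20)))
            expected = len(base_set(a, genome) & base_set(b, genome))
            assert overlap_bp(a, b) == expected
            assert overlap_bp(b, a) == expected  # symmetric


class TestIntervalIndex:
    def test_coverage_matches_overlap(self, genome):
        rng = np.random.default_rng(7)
        base = random_intervals(rng, genome, 25)
        index = IntervalIndex(base, genome)
        for _ in range(50):
            q = random_intervals(rng, genome, 1)[0]
            s, e = genome.to_absolute([q])
            assert int(index.coverage(s, e)[0]) == overlap_bp([q], base)


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(0, 5000, 1e6, 0.0), (10, 1000, 1e6, 10.0), (7, 250, 2e6, 14.0)],
    )
    def test_values(self, count, length, lib, expected):
        assert rpkm(count, length, lib) == pytest.approx(expected)

    def test_linearity(self):
        base = rpkm(5, 700, 3e6)
        assert rpkm(10, 700, 3e6) == pytest.approx(2 * base)
        assert rpkm(5, 1400, 3e6) == pytest.approx(base / 2)
        assert rpkm(5, 700, 6e6) == pytest.approx(base / 2)

    @pytest.mark.parametrize("length,lib", [(0, 1e6), (100, 0)])
    def test_degenerate_inputs(self, length, lib):
        with pytest.raises(ValueError):
            rpkm(1, length, lib)


class TestPearsonOnBins:
    def test_identical(self):
        assert pearson_on_bins([1, 2, 3, 4], [1, 2, 3, 4], 5000) == pytest.approx(1.0)

    def test_anticorrelated(self):
        assert pearson_on_bins([1, 2, 3], [3, 2, 1], 5000) == pytest.approx(-1.0)

    def test_hand_calculation(self):
        a, b = np.array([1.0, 2.0, 4.0]), np.array([2.0, 2.0, 5.0])
        # textbook formula; RPKM normalization is a per-vector rescaling
        expected = np.sum((a - a.mean()) * (b - b.mean())) / (
            np.sqrt(np.sum((a - a.mean()) ** 2)) * np.sqrt(np.sum((b - b.mean()) ** 2))
        )
        assert pearson_on_bins(a, b, 5000) == pytest.approx(expected)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            pearson_on_bins([2, 2, 2], [1, 2, 3], 5000)

    def test_drop_zero_bins_flag(self):
        a, b = [5, 0, 3, 0], [4, 0, 2, 0]
        r_keep = pearson_on_bins(a, b, 1000)
        r_drop = pearson_on_bins(a, b, 1000, drop_zero=True)
        assert r_keep != pytest.approx(r_drop)


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_hand_calculation(self):
        # pooled SD = sqrt(2), difference = -2
        assert cohens_d([0, 2], [2, 4]) == pytest.approx(-math.sqrt(2))

    def test_substantial_effect_threshold(self):
        d = cohens_d([10.0, 11.0, 10.5, 10.2], [8.0, 8.3, 8.1, 8.4])
        assert abs(d) > 0.8  # conventional "substantial" cut

    def test_zero_pooled_sd(self):
        with pytest.raises(ValueError):
            cohens_d([1, 1], [1, 1])


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over fixed-margin tables."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_balanced(self):
        odds, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [[[10, 0], [0, 10]], [[1, 9], [9, 1]]])
    def test_examples_match_enumeration(self, table):
        (a, b), (c, d) = table
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_p_enumeration(a, b, c, d), rel=1e-9)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_p_enumeration(a, b, c, d), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(st.integers(0, 900), st.integers(1, 100)),
        min_size=1,
        max_size=20,
    )
)
def test_union_merge_idempotent_property(pairs):
    ivs = [Interval("chr1", s, s + l) for s, l in pairs]
    merged = union_merge(ivs)
    assert union_merge(merged) == merged
    assert sum(iv.length for iv in merged) == len({p for iv in ivs for p in range(iv.start, iv.end)})
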