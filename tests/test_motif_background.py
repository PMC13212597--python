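"""Summit windows, GC-matched background sampling and hit filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ubptools import simulate as sim
from ubptools.genome import GenomeSpec, Interval, TEAnnotation
from ubptools.motif_background import (
    filter_motif_hits,
    gc_content,
    intersect_ubps_with_subtypes,
    sample_matched_background,
    summit_window,
)


@pytest.fixture(scope="module")
def seq_genome():
    return sim.gen_genome(sim.GenomeParams(1, 100_000, gc=0.45), seed=61)


class TestSummitWindow:
    def test_single_spike_centered(self, seq_genome):
        peak = Interval("chr1", 10_000, 11_000)
        signal = np.zeros(1000)
        signal[400] = 5.0  # summit at 10,400
        mr = summit_window(peak, signal, seq_genome.spec, seq_genome.sequences)
        assert (mr.window.start, mr.window.end) == (10_300, 10_500)
        assert not mr.clamped
        assert len(mr.sequence) == 200
        assert mr.gc == pytest.approx(gc_content(mr.sequence))

    def test_uniform_signal_leftmost_tie(self, seq_genome):
        peak = Interval("chr1", 10_000, 10_500)
        mr = summit_window(peak, np.ones(500), seq_genome.spec)
        # leftmost maximum: window centered on the peak start
        assert mr.window.start == 10_000 - 100

    def test_edge_clamped_and_flagged(self, seq_genome):
        peak = Interval("chr1", 50, 400)
        signal = np.zeros(350)
        signal[0] = 1.0  # summit at position 50
        mr = summit_window(peak, signal, seq_genome.spec)
        assert (mr.window.start, mr.window.end) == (0, 200)
        assert mr.clamped

    def test_empty_signal_rejected(self, seq_genome):
        with pytest.raises(ValueError):
            summit_window(Interval("chr1", 0, 10), [], seq_genome.spec)


class TestIntersectSubtypes:
    @pytest.fixture
    def te(self):
        return TEAnnotation([
            (Interval("chr1", 1000, 2000), "LTR", "IAPEz-int"),
            (Interval("chr1", 5000, 6000), "LINE", "L1Md_A"),
            (Interval("chr1", 9000, 9500), "LTR", "RLTR10"),
        ])

    def test_overlapping_retained(self, te, seq_genome):
        ubps = [Interval("chr1", 1500, 1600), Interval("chr1", 5100, 5200)]
        out = intersect_ubps_with_subtypes(ubps, te, ["IAPEz-int"], seq_genome.spec)
        assert out == [Interval("chr1", 1500, 1600)]

    def test_unknown_subtype_rejected(self, te, seq_genome):
        with pytest.raises(ValueError, match="unknown"):
            intersect_ubps_with_subtypes([], te, ["NoSuchTE"], seq_genome.spec)

    def test_matches_pairwise_oracle(self, te, seq_genome):
        rng = np.random.default_rng(67)
        ubps = [Interval("chr1", int(s), int(s) + 200)
                for s in rng.integers(0, 90_000, 100)]
        subtypes = ["IAPEz-int", "RLTR10"]
        out = intersect_ubps_with_subtypes(ubps, te, subtypes, seq_genome.spec)
        te_ivs = [iv for iv, _, sf in te if sf in subtypes]
        expected = [u for u in ubps if any(u.overlaps(t) for t in te_ivs)]
        assert out == expected


class TestMatchedBackground:
    def make_targets(self, seq_genome, n=30, seed=71):
        rng = np.random.default_rng(seed)
        targets = []
        for i, s in enumerate(rng.integers(0, 90_000, n)):
            peak = Interval("chr1", int(s), int(s) + 400)
            signal = rng.random(400)
            targets.append(summit_window(peak, signal, seq_genome.spec,
                                         seq_genome.sequences, source_id=f"t{i}"))
        return targets

    def test_pool_equals_targets_is_permutation(self, seq_genome):
        targets = self.make_targets(seq_genome)
        pool = [t.window for t in targets]
        bg = sample_matched_background(targets, pool, seq_genome.spec,
                                       seq_genome.sequences, seed=1)
        assert sorted((b.window.start, b.window.end) for b in bg) == \
            sorted((t.window.start, t.window.end) for t in targets)

    def test_bin_histograms_match_exactly(self, seq_genome):
        targets = self.make_targets(seq_genome)
        rng = np.random.default_rng(73)
        pool = [Interval("chr1", int(s), int(s) + 600)
                for s in rng.integers(0, 90_000, 2000)]
        bg = sample_matched_background(targets, pool, seq_genome.spec,
                                       seq_genome.sequences, seed=2)
        assert len(bg) == len(targets)
        assert all(b.window.length == 200 for b in bg)

        def hist(regions):
            bins = {}
            for r in regions:
                b = min(int(r.gc / 0.05), 19)
                bins[b] = bins.get(b, 0) + 1
            return bins

        assert hist(bg) == hist(targets)
        # without replacement: no duplicate pool regions
        keys = [(b.window.start, b.window.end) for b in bg]
        assert len(set(keys)) == len(keys)

    def test_gc_distribution_close_ks(self, seq_genome):
        # Exact bin-level matching pins the two empirical CDFs together at
        # every bin boundary, so the KS distance is bounded by the largest
        # single bin's share of the targets.
        targets = self.make_targets(seq_genome, n=50)
        t_gc = np.array([t.gc for t in targets])
        bin_counts = np.bincount(np.minimum((t_gc / 0.05).astype(int), 19), minlength=20)
        max_bin_share = bin_counts.max() / len(targets)
        rng = np.random.default_rng(79)
        pool = [Interval("chr1", int(s), int(s) + 600)
                for s in rng.integers(0, 90_000, 3000)]
        for seed in range(20):
            bg = sample_matched_background(targets, pool, seq_genome.spec,
                                           seq_genome.sequences, seed=seed)
            b_gc = np.array([b.gc for b in bg])
            ks = sps.ks_2samp(t_gc, b_gc).statistic
            assert ks <= max_bin_share + 1e-9
            # CDFs agree exactly at every bin boundary
            for edge in np.arange(0.05, 1.0, 0.05):
                assert (t_gc < edge).mean() == (b_gc < edge).mean()

    def test_insufficient_bin_named(self, seq_genome):
        targets = self.make_targets(seq_genome, n=10)
        with pytest.raises(ValueError, match=r"GC bin \["):
            sample_matched_background(targets, [], seq_genome.spec,
                                      seq_genome.sequences, seed=1)

    def test_deterministic_given_seed(self, seq_genome):
        targets = self.make_targets(seq_genome)
        rng = np.random.default_rng(83)
        pool = [Interval("chr1", int(s), int(s) + 600)
                for s in rng.integers(0, 90_000, 2000)]
        a = sample_matched_background(targets, pool, seq_genome.spec,
                                      seq_genome.sequences, seed=5)
        b = sample_matched_background(targets, pool, seq_genome.spec,
                                      seq_genome.sequences, seed=5)
        assert [x.window for x in a] == [x.window for x in b]


class TestFilterMotifHits:
    def hits(self, **overrides):
        base = {"motif": ["m1"], "gene": ["g1"], "score": [3.0], "e_value": [1e-12]}
        base.update(overrides)
        return pd.DataFrame(base)

    def test_score_boundary_strict(self):
        out = filter_motif_hits(self.hits(score=[2.0]), {"g1": 100.0})
        assert len(out) == 0

    def test_evalue_boundary_strict(self):
        out = filter_motif_hits(self.hits(e_value=[1e-10]), {"g1": 100.0})
        assert len(out) == 0

    def test_passing_hit(self):
        out = filter_motif_hits(self.hits(), {"g1": 100.0, "g2": 1.0, "g3": 1.0})
        assert len(out) == 1

    def test_expression_rank_matches_sort_oracle(self):
        rng = np.random.default_rng(89)
        genes = [f"g{i}" for i in range(101)]
        expr = {g: float(v) for g, v in zip(genes, rng.uniform(1, 100, 101))}
        hits = pd.DataFrame({"motif": ["m"] * 101, "gene": genes,
                             "score": [3.0] * 101, "e_value": [1e-12] * 101})
        out = filter_motif_hits(hits, expr)
        # oracle: genes at or above the median of expressed genes
        cutoff = float(np.median(list(expr.values())))
        expected = {g for g in genes if expr[g] >= cutoff}
        assert set(out["gene"]) == expected

    def test_missing_gene_listed(self):
        with pytest.raises(KeyError, match="g1"):
            filter_motif_hits(self.hits(), {"other": 5.0})

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(97)
        hits = pd.DataFrame({
            "motif": [f"m{i}" for i in range(50)],
            "gene": [f"g{i}" for i in range(50)],
            "score": rng.uniform(0, 5, 50),
            "e_value": 10.0 ** rng.uniform(-20, 0, 50),
        })
        expr = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0.1, 50, 50))}
        strict = filter_motif_hits(hits, expr, min_score=2.0, max_e=1e-10)
        relaxed = filter_motif_hits(hits, expr, min_score=1.0, max_e=1e-5)
        assert set(strict["motif"]) <= set(relaxed["motif"])
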