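"""Generator contracts: determinism, planted truth, noise calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from ubptools import simulate as sim
from ubptools.genome import Interval, overlap_bp, union_merge


@pytest.fixture(scope="module")
def small_genome():
    return sim.gen_genome(sim.GenomeParams(n_chrom=2, chrom_length=100_000), seed=1)


class TestGenGenome:
    def test_deterministic(self):
        a = sim.gen_genome(sim.GenomeParams(2, 5000), seed=1)
        b = sim.gen_genome(sim.GenomeParams(2, 5000), seed=1)
        assert a.sequences == b.sequences
        assert a.spec == b.spec

    def test_requested_lengths(self):
        g = sim.gen_genome(sim.GenomeParams(1, 10_000), seed=3)
        assert g.spec.chrom_names == ["chr1"]
        assert g.spec.length_of("chr1") == 10_000
        assert len(g.sequences["chr1"]) == 10_000

    def test_seed_changes_sequence(self):
        a = sim.gen_genome(sim.GenomeParams(1, 5000), seed=1)
        b = sim.gen_genome(sim.GenomeParams(1, 5000), seed=2)
        assert a.sequences != b.sequences


class TestGenTeAnnotation:
    def test_counts_and_disjointness(self, small_genome):
        te = sim.gen_te_annotation(
            small_genome.spec,
            {"L1Md_A": sim.TESubfamilySpec("LINE", 50, 400),
             "IAPEz-int": sim.TESubfamilySpec("LTR", 30, 600)},
            seed=5,
        )
        assert len(te.intervals_of(subfamily="L1Md_A")) == 50
        assert len(te.intervals_of(subfamily="IAPEz-int")) == 30
        all_ivs = [iv for iv, _, _ in te]
        merged = union_merge(all_ivs)
        assert sum(iv.length for iv in merged) == sum(iv.length for iv in all_ivs)

    def test_deterministic(self, small_genome):
        spec = {"L1Md_A": sim.TESubfamilySpec("LINE", 20, 400)}
        a = sim.gen_te_annotation(small_genome.spec, spec, seed=9)
        b = sim.gen_te_annotation(small_genome.spec, spec, seed=9)
        assert [(iv, sc, sf) for iv, sc, sf in a] == [(iv, sc, sf) for iv, sc, sf in b]

    def test_infeasible_packing_rejected(self, small_genome):
        with pytest.raises((ValueError, RuntimeError)):
            sim.gen_te_annotation(
                small_genome.spec,
                {"big": sim.TESubfamilySpec("LTR", 2000, 10_000)},
                seed=1,
            )


class TestGenPeaks:
    def test_full_enrichment_containment(self, small_genome):
        te = sim.gen_te_annotation(
            small_genome.spec, {"L1Md_A": sim.TESubfamilySpec("LINE", 60, 800)}, seed=2
        )
        peaks, truth = sim.gen_peaks(
            small_genome.spec,
            sim.PeakParams(count=50, enrichment_fraction=1.0, target_subfamily="L1Md_A"),
            te=te, seed=3,
        )
        target = union_merge(te.intervals_of(subfamily="L1Md_A"))
        # full containment: the peak footprint is entirely inside the target
        footprint = sum(iv.length for iv in union_merge(peaks.intervals))
        assert overlap_bp(peaks.intervals, target) == footprint
        assert truth["planted_in_target"].all()

    def test_planted_fraction_counts(self, small_genome):
        te = sim.gen_te_annotation(
            small_genome.spec, {"L1Md_A": sim.TESubfamilySpec("LINE", 60, 800)}, seed=2
        )
        peaks, truth = sim.gen_peaks(
            small_genome.spec,
            sim.PeakParams(count=200, enrichment_fraction=0.5, target_subfamily="L1Md_A"),
            te=te, seed=4,
        )
        assert int(truth["planted_in_target"].sum()) == 100
        assert len(truth) == len(peaks) == 200

    def test_blacklist_avoided(self, small_genome):
        from ubptools.genome import Blacklist

        blacklist = Blacklist([Interval("chr1", 0, 50_000)])
        peaks, _ = sim.gen_peaks(
            small_genome.spec, sim.PeakParams(count=50), seed=5, blacklist=blacklist
        )
        assert overlap_bp(peaks.intervals, list(blacklist)) == 0


class TestGenReads:
    def make(self, small_genome, **kwargs):
        snps = sim.gen_snp_table(small_genome, snp_density=2.0, seed=11)
        params = sim.ReadParams(count=kwargs.pop("count", 200), length=4000, **kwargs)
        obs, truth = sim.gen_reads_with_snps(
            small_genome, snps, params,
            maternal_fraction=kwargs.pop("maternal_fraction", 0.5), seed=7,
        )
        return snps, obs, truth

    def test_noiseless_reads_match_origin(self, small_genome):
        snps, obs, truth = self.make(small_genome)
        lookup = {(c, p): (m, f) for c, p, m, f in zip(
            snps["chrom"], snps["pos"], snps["maternal"], snps["paternal"])}
        origin = dict(zip(truth["read_id"], truth["origin"]))
        for row in obs.itertuples(index=False):
            mat, pat = lookup[(row.chrom, row.pos)]
            expected = mat if origin[row.read_id] == "maternal" else pat
            assert row.base == expected

    def test_full_deletion_rate(self, small_genome):
        _, obs, _ = self.make(small_genome, n_deletion_rate=1.0)
        assert (obs["base"] == "DEL").all()

    def test_origin_mix_binomial(self, small_genome):
        _, _, truth = self.make(small_genome, count=1000)
        n_mat = int((truth["origin"] == "maternal").sum())
        lo, hi = sps.binom.interval(0.99, 1000, 0.5)
        assert lo <= n_mat <= hi

    def test_truth_complete(self, small_genome):
        _, obs, truth = self.make(small_genome, count=150)
        assert len(truth) == 150
        assert set(obs["read_id"]) <= set(truth["read_id"])


class TestGenExpression:
    def test_planted_classes_satisfy_rules(self):
        stage, _, _, truth = sim.gen_expression(sim.ExprParams(), seed=13)
        for row, cls in zip(stage.itertuples(index=False), truth["zga_class"]):
            if cls == "minor":
                assert row.FGO < 5 and row.MII < 5
                baseline = max(row.FGO, row.MII) + 0.5
                assert row.c1 > 5 and row.e2c > 5
                assert row.c1 >= 3 * baseline and row.e2c >= 3 * baseline
            elif cls == "major":
                assert (row.FGO + row.MII) / 2 > 5
                assert row.l2c > 5 * (row.FGO + row.MII) / 2

    def test_planted_downregulation_fold(self):
        _, wt, ko, truth = sim.gen_expression(
            sim.ExprParams(n_down=40, fold_down=4.0, noise_cv=0.05, n_reps=4), seed=17
        )
        down = truth["true_down"].to_numpy()
        log2fc = np.log2(ko.mean(axis=1).to_numpy() / wt.mean(axis=1).to_numpy())
        assert np.abs(log2fc[down].mean() + 2.0) < 0.1
        assert np.abs(log2fc[~down]).mean() < 0.1


class TestGenMethylation:
    @pytest.mark.parametrize("level,expect", [(1.0, 1.0), (0.0, 0.0)])
    def test_degenerate_levels(self, small_genome, level, expect):
        spec = [sim.MethRegionSpec(Interval("chr1", 0, 20_000), "WCG", level, 500)]
        calls, _ = sim.gen_methylation(small_genome, spec, seed=3)
        assert calls["methylated"].mean() == expect
        assert (calls["context"] == "WCG").all()

    def test_intermediate_level_binomial(self, small_genome):
        spec = [sim.MethRegionSpec(Interval("chr1", 0, 50_000), "WCG", 0.3, 10_000)]
        calls, _ = sim.gen_methylation(small_genome, spec, seed=5)
        assert abs(calls["methylated"].mean() - 0.3) < 0.02

    def test_context_consistent_with_sequence(self, small_genome):
        from ubptools.meth_summary import call_context

        spec = [sim.MethRegionSpec(Interval("chr1", 1000, 9000), "GCH", 0.5, 200)]
        calls, _ = sim.gen_methylation(small_genome, spec, seed=7)
        seq = small_genome.sequences["chr1"]
        for row in calls.drop_duplicates(subset=["pos", "strand"]).itertuples(index=False):
            assert call_context(seq, row.pos, row.strand) == "GCH"
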