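import numpy as np
import pandas as pd
import pytest

from _oracles import Bitmap, random_intervals
from binmeth import intervals
from binmeth.io_formats import GenomeIndex
from binmeth.regions import (
    build_partition,
    distribute_regions,
    flank_associate,
    merged_total_bp,
    overlap_sets,
    percent_overlap,
    promoter_methylation,
    recovery_metrics,
    state_distribution,
    state_enrichment,
)

GENOME = GenomeIndex(("chr1",), {"chr1": 200})


def regions_df(rows, chrom="chr1"):
    return pd.DataFrame(
        [(chrom, s, e) for s, e in rows], columns=["chrom", "start", "end"]
    )


def features_df(rows):
    """rows: (start, end, kind)"""
    return pd.DataFrame(
        [("chr1", s, e, "+", k, f"f{i}") for i, (s, e, k) in enumerate(rows)],
        columns=["chrom", "start", "end", "strand", "kind", "id"],
    )


class TestPartition:
    def test_worked_example(self):
        part = build_partition(
            features_df([(0, 100, "gene"), (50, 150, "TE")]), GENOME
        )
        as_tuples = {
            cls: [(r.start, r.end) for r in df.itertuples()]
            for cls, df in part.items()
        }
        assert as_tuples == {
            "gene": [(0, 50)],
            "gene/TE": [(50, 100)],
            "TE": [(100, 150)],
            "intergenic": [(150, 200)],
        }

    def test_no_features_all_intergenic(self):
        part = build_partition(features_df([]), GENOME)
        assert merged_total_bp(part["intergenic"]) == 200
        assert all(
            merged_total_bp(part[c]) == 0 for c in ("gene", "TE", "gene/TE")
        )

    def test_identical_gene_te(self):
        part = build_partition(
            features_df([(10, 60, "gene"), (10, 60, "TE")]), GENOME
        )
        assert merged_total_bp(part["gene/TE"]) == 50
        assert merged_total_bp(part["gene"]) == 0
        assert merged_total_bp(part["TE"]) == 0

    def test_tiles_genome_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            feats = features_df(
                [
                    (s, e, k)
                    for (s, e), k in zip(
                        random_intervals(rng, 8, 200),
                        rng.choice(["gene", "TE"], size=8),
                    )
                ]
            )
            part = build_partition(feats, GENOME)
            total = sum(merged_total_bp(df) for df in part.values())
            assert total == 200
            # pairwise disjoint
            classes = list(part)
            for i, c1 in enumerate(classes):
                for c2 in classes[i + 1 :]:
                    ov = overlap_sets(part[c1], part[c2])
                    assert ov["overlap_bp"] == 0

    def test_feature_beyond_chromosome_errors(self):
        with pytest.raises(ValueError):
            build_partition(features_df([(100, 300, "gene")]), GENOME)


class TestDistribute:
    def test_entirely_te(self):
        part = build_partition(features_df([(0, 100, "TE")]), GENOME)
        fracs, n = distribute_regions(regions_df([(10, 50)]), part)
        assert fracs["TE"] == 1.0
        assert n == 1

    def test_half_and_half(self):
        part = build_partition(features_df([(0, 100, "gene")]), GENOME)
        fracs, _ = distribute_regions(regions_df([(50, 150)]), part)
        assert fracs["gene"] == pytest.approx(0.5)
        assert fracs["intergenic"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        part = build_partition(
            features_df([(0, 80, "gene"), (60, 120, "TE")]), GENOME
        )
        regs = regions_df(random_intervals(rng, 10, 200))
        fracs, _ = distribute_regions(regs, part)
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_regions(self):
        part = build_partition(features_df([]), GENOME)
        fracs, n = distribute_regions(regions_df([]), part)
        assert n == 0
        assert all(v == 0.0 for v in fracs.values())


class TestOverlapSets:
    def test_basic(self):
        ov = overlap_sets(regions_df([(0, 100)]), regions_df([(50, 150)]))
        assert ov["n_a_overlapping_b"] == 1
        assert ov["overlap_bp"] == 50
        assert ov["jaccard_bp"] == pytest.approx(50 / 150)

    def test_disjoint(self):
        ov = overlap_sets(regions_df([(0, 10)]), regions_df([(50, 60)]))
        assert ov["n_a_overlapping_b"] == 0
        assert ov["n_shared_pairs"] == 0
        assert ov["overlap_bp"] == 0

    def test_containment(self):
        ov = overlap_sets(regions_df([(20, 40)]), regions_df([(0, 100)]))
        assert ov["overlap_bp"] == ov["total_bp_a"] == 20

    def test_symmetric_overlap_bp(self):
        rng = np.random.default_rng(4)
        a = regions_df(random_intervals(rng, 10, 500))
        b = regions_df(random_intervals(rng, 10, 500))
        assert overlap_sets(a, b)["overlap_bp"] == overlap_sets(b, a)["overlap_bp"]

    def test_min_bp(self):
        ov = overlap_sets(regions_df([(0, 100)]), regions_df([(95, 200)]), min_bp=10)
        assert ov["n_a_overlapping_b"] == 0

    def test_bitmap_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a_iv = random_intervals(rng, int(rng.integers(1, 12)), 300)
            b_iv = random_intervals(rng, int(rng.integers(1, 12)), 300)
            ov = overlap_sets(regions_df(a_iv), regions_df(b_iv))
            bm_a, bm_b = Bitmap(300, a_iv), Bitmap(300, b_iv)
            assert ov["overlap_bp"] == (bm_a & bm_b).total()
            assert ov["total_bp_a"] == bm_a.total()
            n_overlap = sum(
                1 for s, e in a_iv if any(min(e, be) > max(s, bs) for bs, be in b_iv)
            )
            assert ov["n_a_overlapping_b"] == n_overlap


class TestPercentOverlap:
    def test_printed_share(self):
        assert percent_overlap(6117, 6670) == 91.7

    def test_printed_hyper_share(self):
        assert percent_overlap(3608, 6394) == 56.4

    def test_zero_numerator(self):
        assert percent_overlap(0, 10) == 0.0

    def test_half_up_rounding(self):
        assert percent_overlap(1, 8, digits=1) == 12.5
        assert percent_overlap(125, 1000, digits=0) == 13.0

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            percent_overlap(5, 0)


class TestFlankAssociate:
    def test_within_flank(self):
        feats = features_df([(5000, 6000, "gene")])
        regs = regions_df([(4400, 4600)])  # 400 bp upstream
        pairs, summary = flank_associate(feats, regs, flank=1000)
        assert summary["n_pairs"] == 1

    def test_outside_flank(self):
        feats = features_df([(5000, 6000, "gene")])
        regs = regions_df([(3000, 3500)])  # 1500 bp away
        _, summary = flank_associate(feats, regs, flank=1000)
        assert summary["n_pairs"] == 0

    def test_one_region_two_features(self):
        feats = features_df([(1000, 2000, "gene"), (2500, 3500, "gene")])
        regs = regions_df([(2100, 2400)])
        pairs, summary = flank_associate(feats, regs, flank=1000)
        assert summary["n_pairs"] == 2
        assert summary["n_features"] == 2
        assert summary["n_regions"] == 1


class TestPromoterMethylation:
    def _cx(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"]
        )

    def test_plus_strand_window(self):
        feats = features_df([(5000, 6000, "gene")])
        cx = self._cx(
            [("chr1", 4500, "+", "CHH", 3, 7), ("chr1", 5500, "+", "CHH", 9, 1)]
        )
        out = promoter_methylation(feats, {"s1": cx}, flank=1000)
        rec = out.iloc[0]
        assert (rec.promoter_start, rec.promoter_end) == (4000, 5000)
        assert rec.level == pytest.approx(0.3)  # body cytosine excluded

    def test_minus_strand_window(self):
        feats = features_df([(5000, 6000, "gene")])
        feats["strand"] = "-"
        cx = self._cx([("chr1", 6500, "+", "CG", 4, 4)])
        out = promoter_methylation(feats, {"s1": cx}, flank=1000)
        rec = out.iloc[0]
        assert (rec.promoter_start, rec.promoter_end) == (6000, 7000)
        assert rec.level == pytest.approx(0.5)

    def test_all_unmethylated(self):
        feats = features_df([(2000, 3000, "gene")])
        cx = self._cx([("chr1", 1500, "+", "CG", 0, 12)])
        out = promoter_methylation(feats, {"s1": cx})
        assert out.iloc[0].level == 0.0

    def test_missing_strand_errors(self):
        feats = features_df([(2000, 3000, "gene")])
        feats["strand"] = "."
        with pytest.raises(ValueError):
            promoter_methylation(feats, {})


class TestStateEnrichment:
    def _states(self, seg_len=20):
        # states 1..9 tile [0, 180); state fractions equal
        rows = []
        for i in range(9):
            rows.append(("chr1", i * seg_len, (i + 1) * seg_len, i + 1))
        rows.append(("chr1", 180, 200, 1))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])

    def test_whole_genome_fold_is_one(self):
        states = self._states()
        whole = regions_df([(0, 200)])
        enr = state_enrichment(whole, states, GENOME)
        assert enr["fold"].values == pytest.approx(np.ones(9))

    def test_concentrated_regions_fold(self):
        # all region bp inside state 5 which occupies 10% of the genome
        states = self._states()
        regs = regions_df([(80, 100)])  # exactly state 5's segment
        enr = state_enrichment(regs, states, GENOME)
        rec = enr[enr.state == 5].iloc[0]
        assert rec.fold == pytest.approx(10.0)

    def test_extreme_binomial_tail(self):
        # 100 units of 100 bp all inside a state covering 10% of the genome
        genome = GenomeIndex(("chr1",), {"chr1": 100_000})
        rows = [("chr1", 0, 10_000, 8)]
        pos = 10_000
        for i in range(9):
            rows.append(("chr1", pos, pos + 10_000, i + 1 if i + 1 != 8 else 9))
            pos += 10_000
        states = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])[
            lambda d: d.end <= 100_000
        ]
        regs = regions_df([(0, 10_000)])
        enr = state_enrichment(regs, states, genome)
        rec = enr[enr.state == 8].iloc[0]
        assert np.log10(rec.p) == pytest.approx(100 * np.log10(0.1), rel=1e-6)

    def test_uniform_null(self):
        rng = np.random.default_rng(6)
        genome = GenomeIndex(("chr1",), {"chr1": 90_000})
        rows = []
        for i in range(9):
            rows.append(("chr1", i * 10_000, (i + 1) * 10_000, i + 1))
        states = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        starts = rng.integers(0, 89_000, size=200)
        regs = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 500}
        )
        enr = state_enrichment(regs, states, genome)
        assert (enr.q > 0.05).sum() >= 8  # no systematic enrichment

    def test_distribution_table(self):
        states = self._states()
        regs = regions_df([(0, 40)])  # states 1 and 2
        dist = state_distribution(regs, states, GENOME)
        assert dist.loc[dist.state == 1, "region_fraction"].iloc[0] == pytest.approx(0.5)
        assert dist.loc[dist.state == 2, "region_fraction"].iloc[0] == pytest.approx(0.5)


class TestIntervalPrimitives:
    def test_bitmap_oracle_equivalence(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a_iv = random_intervals(rng, int(rng.integers(1, 15)), 400)
            b_iv = random_intervals(rng, int(rng.integers(1, 15)), 400)
            a_s = np.array([s for s, _ in a_iv])
            a_e = np.array([e for _, e in a_iv])
            b_s = np.array([s for s, _ in b_iv])
            b_e = np.array([e for _, e in b_iv])
            bm_a, bm_b = Bitmap(400, a_iv), Bitmap(400, b_iv)
            ms, me = intervals.merge(a_s, a_e)
            assert list(zip(ms, me)) == bm_a.intervals()
            is_, ie = intervals.intersect(a_s, a_e, b_s, b_e)
            assert list(zip(is_, ie)) == (bm_a & bm_b).intervals()
            ss, se = intervals.subtract(a_s, a_e, b_s, b_e)
            assert list(zip(ss, se)) == (bm_a - bm_b).intervals()
            cs, ce = intervals.complement(a_s, a_e, 400)
            assert list(zip(cs, ce)) == (~bm_a).intervals()
            cov = intervals.coverage(a_s, a_e, *intervals.merge(b_s, b_e))
            for (s, e), c in zip(a_iv, cov):
                assert c == int(np.sum(bm_b.mask[s:e]))

    def test_merge_gap(self):
        s, e = intervals.merge([0, 150], [100, 200], gap=50)
        assert list(s) == [0] and list(e) == [200]
        s, e = intervals.merge([0, 151], [100, 200], gap=50)
        assert list(s) == [0, 151]


class TestRecoveryMetrics:
    def test_exact_recovery(self):
        truth = regions_df([(0, 100), (500, 600)])
        called = regions_df([(0, 100), (500, 600)])
        m = recovery_metrics(called, truth)
        assert m["sensitivity"] == 1.0 and m["precision"] == 1.0

    def test_half_coverage_threshold(self):
        truth = regions_df([(0, 100)])
        called = regions_df([(50, 100)])  # covers exactly 50%
        m = recovery_metrics(called, truth)
        assert m["sensitivity"] == 1.0  # >= 50% counts

    def test_miss(self):
        truth = regions_df([(0, 100)])
        called = regions_df([(90, 300)])  # only 10% of called inside truth
        m = recovery_metrics(called, truth)
        assert m["sensitivity"] == 0.0
        assert m["precision"] == 0.0
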