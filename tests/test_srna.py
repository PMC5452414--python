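import numpy as np
import pandas as pd
import pytest

from binmeth.io_formats import FormatError, GenomeIndex
from binmeth.srna import (
    bin_and_normalize,
    call_degs,
    call_dsrs,
    delta_scatter,
    filter_srna_reads,
    read_bin_table,
    read_srna_bed,
    write_bin_table,
    write_srna_bed,
)

GENOME = GenomeIndex(("chr1",), {"chr1": 100_000})


def make_reads(rows):
    """rows: (chrom, start, end, length, n_hits, strand)"""
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "length", "n_hits", "strand"]
    )


def make_bins(rows, total):
    """rows: (start, count)"""
    df = pd.DataFrame(rows, columns=["start", "count"])
    df["chrom"] = "chr1"
    df["end"] = df["start"] + 100
    df["rptm"] = df["count"] * 1e7 / total
    return df[["chrom", "start", "end", "count", "rptm"]]


class TestFilter:
    def test_structural_mask_removes(self):
        reads = make_reads([("chr1", 500, 524, 24, 1, "+")])
        mask = pd.DataFrame({"chrom": ["chr1"], "start": [400], "end": [600]})
        out, total = filter_srna_reads(reads, mask)
        assert total == 0 and out.empty

    def test_off_target_length_in_total_but_not_bins(self):
        reads = make_reads(
            [("chr1", 100, 121, 21, 1, "+"), ("chr1", 200, 224, 24, 1, "+")]
        )
        out, total = filter_srna_reads(reads)
        assert total == 2  # 21-nt read counts toward the RPTM denominator
        bins = bin_and_normalize(out, GENOME, total)
        assert bins["count"].sum() == 1  # only the 24-nt read is binned

    def test_multimapper_removed(self):
        reads = make_reads([("chr1", 100, 124, 24, 3, "+")])
        out, total = filter_srna_reads(reads)
        assert total == 0

    def test_out_of_size_range_removed(self):
        reads = make_reads([("chr1", 100, 117, 17, 1, "+")])
        _, total = filter_srna_reads(reads)
        assert total == 0

    def test_missing_length_errors(self):
        with pytest.raises(FormatError):
            filter_srna_reads(pd.DataFrame({"chrom": ["chr1"], "start": [0]}))


class TestBinAndNormalize:
    def test_rptm_arithmetic(self):
        reads = make_reads([("chr1", 100, 124, 24, 1, "+")] * 12)
        bins = bin_and_normalize(reads, GENOME, total_mapped=6_000_000)
        assert bins.iloc[0].rptm == pytest.approx(20.0)

    def test_zero_reads(self):
        reads = make_reads([])
        bins = bin_and_normalize(reads, GENOME, total_mapped=100)
        assert bins.empty

    def test_five_prime_rule_boundary(self):
        # plus-strand read spanning a bin boundary, 5' end at 199
        reads = make_reads([("chr1", 199, 223, 24, 1, "+")])
        bins = bin_and_normalize(reads, GENOME, total_mapped=100)
        assert (bins.iloc[0].start, bins.iloc[0].end) == (100, 200)

    def test_five_prime_minus_strand(self):
        # minus-strand: 5' end is end-1
        reads = make_reads([("chr1", 180, 204, 24, 1, "-")])
        bins = bin_and_normalize(reads, GENOME, total_mapped=100)
        assert bins.iloc[0].start == 200

    def test_read_beyond_chromosome_errors(self):
        reads = make_reads([("chr1", 99_990, 100_014, 24, 1, "-")])
        with pytest.raises(FormatError):
            bin_and_normalize(reads, GENOME, total_mapped=100)

    def test_bed_roundtrip(self, tmp_path):
        reads = make_reads(
            [("chr1", 100, 124, 24, 1, "+"), ("chr1", 300, 321, 21, 4, "-")]
        )
        write_srna_bed(reads, tmp_path / "r.bed")
        back = read_srna_bed(tmp_path / "r.bed")
        pd.testing.assert_frame_equal(back, reads)

    def test_bin_table_roundtrip(self, tmp_path):
        bins = make_bins([(0, 5), (100, 2)], total=1000)
        write_bin_table(bins, 1000, tmp_path / "b.tsv")
        back, total = read_bin_table(tmp_path / "b.tsv")
        assert total == 1000
        pd.testing.assert_frame_equal(back, bins)


class TestCallDsrs:
    def test_rptm_filter_strict(self):
        # RPTM exactly 5.0 in one sample, 4.0 in the other: not retained
        wt = make_bins([(0, 5)], total=10_000_000)
        mut = make_bins([(0, 4)], total=10_000_000)
        tested, dsrs = call_dsrs(wt, mut, 10_000_000, 10_000_000)
        assert tested.empty and dsrs.empty

    def test_extreme_down(self):
        wt = make_bins([(0, 100)], total=1_000_000)
        mut = make_bins([], total=1_000_000)
        tested, dsrs = call_dsrs(wt, mut, 1_000_000, 1_000_000)
        assert len(dsrs) == 1
        assert dsrs.iloc[0].direction == "down"
        assert dsrs.iloc[0].p == pytest.approx(2 * 0.5**100, rel=1e-9)

    def test_equal_counts_never_dsr(self):
        wt = make_bins([(0, 80)], total=1_000_000)
        mut = make_bins([(0, 80)], total=1_000_000)
        tested, dsrs = call_dsrs(wt, mut, 1_000_000, 1_000_000)
        assert tested.iloc[0].p == 1.0
        assert dsrs.empty

    def test_adjacent_bins_merge(self):
        wt = make_bins([(0, 100), (100, 100)], total=1_000_000)
        mut = make_bins([], total=1_000_000)
        _, dsrs = call_dsrs(wt, mut, 1_000_000, 1_000_000)
        assert len(dsrs) == 1
        assert (dsrs.iloc[0].start, dsrs.iloc[0].end, dsrs.iloc[0].n_bins) == (0, 200, 2)

    def test_non_adjacent_bins_stay_separate(self):
        wt = make_bins([(0, 100), (200, 100)], total=1_000_000)
        mut = make_bins([], total=1_000_000)
        _, dsrs = call_dsrs(wt, mut, 1_000_000, 1_000_000)
        assert len(dsrs) == 2

    def test_scaling_invariance(self):
        wt = make_bins([(0, 40), (100, 10)], total=1_000_000)
        mut = make_bins([(0, 10), (100, 40)], total=1_000_000)
        t1, _ = call_dsrs(wt, mut, 1_000_000, 1_000_000)
        wt5 = make_bins([(0, 200), (100, 50)], total=5_000_000)
        mut5 = make_bins([(0, 50), (100, 200)], total=5_000_000)
        t5, _ = call_dsrs(wt5, mut5, 5_000_000, 5_000_000)
        assert t1.rptm_wt.values == pytest.approx(t5.rptm_wt.values)

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            call_dsrs(make_bins([], 1), make_bins([], 1), 0, 10)

    def test_null_fdr_calibration(self):
        # 10,000 null bins with equal Poisson rates: fraction q < 0.01 must
        # not exceed 0.01 + 3*SE
        rng = np.random.default_rng(77)
        n = 10_000
        genome = GenomeIndex(("chr1",), {"chr1": n * 100})
        counts_wt = rng.poisson(30, size=n)
        counts_mut = rng.poisson(30, size=n)
        starts = np.arange(n) * 100
        total = 10_000_000
        wt = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 100, "count": counts_wt}
        )
        wt["rptm"] = wt["count"] * 1e7 / total
        mut = wt.copy()
        mut["count"] = counts_mut
        mut["rptm"] = mut["count"] * 1e7 / total
        tested, _ = call_dsrs(wt, mut, total, total)
        frac = tested["significant"].mean()
        se = np.sqrt(0.01 * 0.99 / len(tested))
        assert frac <= 0.01 + 3 * se


class TestCallDegs:
    def _counts(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "kind", "count_wt", "count_mut"])

    def test_strong_up(self):
        rows = [("g0", "gene", 100, 10)] + [
            (f"g{i}", "gene", 50, 50) for i in range(1, 40)
        ]
        out = call_degs(self._counts(rows))
        rec = out.iloc[0]
        assert rec.fold_change == pytest.approx(10.0, rel=0.05)
        assert rec.status == "down"  # mutant lower

    def test_fold_cutoff_conjunctive(self):
        # normalised fold ~1.5 with overwhelming counts: significant p but ns
        rows = [("g0", "gene", 2000, 3000)] + [
            (f"g{i}", "gene", 1000, 1000) for i in range(1, 101)
        ]
        out = call_degs(self._counts(rows))
        rec = out.iloc[0]
        assert rec.q < 0.05
        assert 1.3 < rec.fold_change < 2
        assert rec.status == "ns"

    def test_zero_zero_untested(self):
        rows = [("g0", "gene", 0, 0), ("g1", "gene", 10, 10)]
        out = call_degs(self._counts(rows))
        assert np.isnan(out.iloc[0].p)
        assert out.iloc[0].status == "ns"

    def test_all_zero_matrix(self):
        out = call_degs(self._counts([("g0", "gene", 0, 0)]))
        assert (out.status == "ns").all()

    def test_planted_te_derepression(self):
        # enough genes that planted effects barely distort library sizes
        from binmeth.simulate import SimConfig, simulate_expression, simulate_genome

        truth = simulate_genome(
            SimConfig(
                genome_size=500_000,
                n_rddm_loci=30,
                n_het_loci=10,
                n_genes=80,
                n_de_genes=10,
                n_derepressed_te=8,
                seed=13,
            )
        )
        wt = simulate_expression(truth, "WT", seed=1)
        mut = simulate_expression(truth, "pkl", seed=2)
        counts = wt.rename(columns={"count": "count_wt"})
        counts["count_mut"] = mut["count"]
        out = call_degs(counts)
        planted_up = set(
            truth.expression.loc[truth.expression.de_status_pkl == "up", "feature_id"]
        )
        called_up = set(out.loc[out.status == "up", "feature_id"])
        # most planted up-regulated features are recovered
        assert len(called_up & planted_up) / len(planted_up) >= 0.8


class TestDeltaScatter:
    def _cx(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"]
        )

    def test_identical_samples_flagged(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        cx = self._cx([("chr1", 10, "+", "CHH", 5, 5)])
        bins = make_bins([(0, 10)], total=1000)
        table, corr = delta_scatter(regions, cx, cx, bins, bins, 1000, 1000)
        assert table.iloc[0].delta_log_rptm == 0.0
        assert table.iloc[0].delta_CHH == 0.0
        assert not table.iloc[0].ok_CG  # no CG cytosines -> flagged
        assert corr.empty  # constant deltas: correlation undefined

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_monotone_coupling(self, small_truth, sign):
        # plant a per-locus effect strength that couples siRNA change and
        # CHH change monotonically (anti-monotonically for sign = -1)
        import dataclasses

        from binmeth.simulate import simulate_methylome, simulate_srna_library

        loci = small_truth.loci.copy()
        rddm = loci["class"].isin(["RdDM", "RdDM_low"]).to_numpy()
        n = int(rddm.sum())
        strength = np.linspace(0.25, 1.0, n)
        loci.loc[rddm, "level_CHH_WT"] = 0.40
        loci.loc[rddm, "level_CHH_pkl"] = np.clip(0.40 - sign * 0.35 * strength, 0.01, 0.9)
        loci.loc[rddm, "srna_WT"] = 200.0
        loci.loc[rddm, "srna_pkl"] = 200.0 * 6.0 ** (-strength)
        truth = dataclasses.replace(small_truth, loci=loci)
        wt_cx = simulate_methylome(truth, "WT", seed=11)
        mut_cx = simulate_methylome(truth, "pkl", seed=12)
        wt_b, wt_t = simulate_srna_library(truth, "WT", seed=11)
        mut_b, mut_t = simulate_srna_library(truth, "pkl", seed=12)
        regions = loci.loc[rddm, ["chrom", "start", "end"]]
        table, corr = delta_scatter(
            regions, wt_cx, mut_cx, wt_b, mut_b, wt_t, mut_t
        )
        chh = corr.loc[corr.context == "CHH"]
        assert len(chh) == 1
        if sign > 0:
            assert chh.iloc[0].spearman >= 0.9
        else:
            assert chh.iloc[0].spearman <= -0.9
        assert chh.iloc[0].n == n
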