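"""Peak ingestion, regulome partition, hub track, GC background."""

import warnings

import numpy as np
import pandas as pd
import pytest

from rbpscore.context import (
    GCBackground, VariantPanel, _merge_small_groups, bin_gc_percent,
    build_gc_background, build_hub_track, load_peaks, partition_by_coding,
)
from rbpscore.intervals import IntervalSet
from rbpscore import io as rio


def write_narrowpeak(path, rows):
    with open(path, "w") as fh:
        for chrom, s, e, name, score, strand in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t{strand}"
                     "\t0\t-1\t-1\t-1\n")


class TestLoadPeaks:
    def test_score_filter_and_blacklist(self, tmp_path):
        f = tmp_path / "RBPX_K562_rep1.narrowPeak"
        write_narrowpeak(f, [
            ("chr1", 100, 200, "inside_blacklist", 1000, "+"),
            ("chr1", 400, 500, "low_score", 800, "+"),
            ("chr1", 600, 700, "kept", 1000, "+"),
        ])
        blacklist = IntervalSet.from_intervals([("chr1", 50, 300)])
        colls = load_peaks([f], min_score=1000, blacklist=blacklist)
        peaks = colls["RBPX"].peaks
        assert len(peaks) == 1
        assert (peaks.iloc[0].start, peaks.iloc[0].end) == (600, 700)

    def test_replicates_merge_same_strand(self, tmp_path):
        f1 = tmp_path / "RBPX_K562_rep1.narrowPeak"
        f2 = tmp_path / "RBPX_K562_rep2.narrowPeak"
        write_narrowpeak(f1, [("chr1", 100, 200, "a", 1000, "+")])
        write_narrowpeak(f2, [("chr1", 150, 250, "b", 1000, "+")])
        colls = load_peaks([f1, f2], min_score=1000)
        peaks = colls["RBPX"].peaks
        assert len(peaks) == 1
        assert (peaks.iloc[0].start, peaks.iloc[0].end) == (100, 250)

    def test_score_threshold_modes(self, tmp_path):
        f = tmp_path / "RBPY_HepG2_rep1.narrowPeak"
        write_narrowpeak(f, [("chr1", 0, 50, "a", 1200, "+")])
        assert load_peaks([f], 1000, score_exact=True)["RBPY"].peaks.empty
        assert len(load_peaks([f], 1000, score_exact=False)["RBPY"].peaks) == 1

    def test_malformed_line_names_file_and_line(self, tmp_path):
        f = tmp_path / "RBPZ_K562_rep1.narrowPeak"
        f.write_text("chr1\t100\t200\tok\t1000\t+\t0\t-1\t-1\t-1\n"
                     "chr1\tnotanint\t300\tbad\t1000\t+\t0\t-1\t-1\t-1\n")
        with pytest.raises(rio.ParseError, match=r"rep1\.narrowPeak:2"):
            load_peaks([f], 1000)

    def test_empty_after_filter_warns_not_errors(self, tmp_path):
        f = tmp_path / "RBPW_K562_rep1.narrowPeak"
        write_narrowpeak(f, [("chr1", 0, 50, "a", 200, "+")])
        with pytest.warns(UserWarning, match="no peaks retained"):
            colls = load_peaks([f], 1000)
        assert colls["RBPW"].peaks.empty


class TestPartition:
    def collections(self, peak_rows):
        df = pd.DataFrame(peak_rows,
                          columns=["chrom", "start", "end", "strand", "score"])
        from rbpscore.context import RBPPeakCollection
        return {"R": RBPPeakCollection("R", ("X",), df)}

    def test_split_at_cds_boundary(self):
        colls = self.collections([("chr1", 100, 200, "+", 1000.0)])
        cds = IntervalSet.from_intervals([("chr1", 150, 300)])
        part = partition_by_coding(colls, cds)
        assert list(part.coding["R"].intervals()) == [("chr1", 150, 200)]
        assert list(part.noncoding["R"].intervals()) == [("chr1", 100, 150)]

    def test_intronic_peak_all_noncoding(self):
        colls = self.collections([("chr1", 100, 200, "+", 1000.0)])
        cds = IntervalSet.from_intervals([("chr1", 5000, 5100)])
        part = partition_by_coding(colls, cds)
        assert not part.coding["R"]
        assert part.noncoding["R"].total_length == 100

    def test_peak_spanning_two_cds_exons(self):
        """Per-base membership oracle: coding, intronic, coding segments."""
        colls = self.collections([("chr1", 100, 400, "+", 1000.0)])
        cds = IntervalSet.from_intervals([("chr1", 50, 150), ("chr1", 300, 500)])
        part = partition_by_coding(colls, cds)
        # brute-force per-base assignment
        coding = {p for p in range(100, 400) if 50 <= p < 150 or 300 <= p < 500}
        got_cod = {p for c, s, e in part.coding["R"].intervals()
                   for p in range(s, e)}
        got_non = {p for c, s, e in part.noncoding["R"].intervals()
                   for p in range(s, e)}
        assert got_cod == coding
        assert got_non == set(range(100, 400)) - coding

    def test_footprint_conservation_on_world(self, small_world):
        cds = rio.cds_footprint(small_world.annotation)
        part = partition_by_coding(small_world.collections, cds)
        for rbp, coll in small_world.collections.items():
            total = coll.footprint.total_length
            assert (part.coding[rbp].total_length
                    + part.noncoding[rbp].total_length) == total


class TestHubTrack:
    def test_examples(self):
        from rbpscore.context import RBPPeakCollection

        def coll(rbp, rows):
            return RBPPeakCollection(rbp, ("X",), pd.DataFrame(
                rows, columns=["chrom", "start", "end", "strand", "score"]
            ))

        a = coll("A", [("chr1", 0, 10, "+", 1000.0)])
        b = coll("B", [("chr1", 5, 15, "+", 1000.0)])
        runs = build_hub_track({"A": a, "B": b})
        assert runs.count_at("chr1", 2) == 1
        assert runs.count_at("chr1", 7) == 2
        assert runs.count_at("chr1", 12) == 1

        # replicate peaks of one RBP are merged before counting: H stays 1
        a2 = coll("A", [("chr1", 0, 10, "+", 1000.0),
                        ("chr1", 5, 12, "-", 1000.0)])
        runs = build_hub_track({"A": a2})
        assert runs.count_at("chr1", 7) == 1


class TestGCBackground:
    def panel(self, rows):
        return VariantPanel(pd.DataFrame(
            rows, columns=["chrom", "pos0", "ref", "alt", "daf"]
        ))

    def test_direct_counting(self):
        genome = {"chr1": "ACGT" * 250}  # 1 kb, GC 50 everywhere
        panel = self.panel([
            ("chr1", 10, "A", "C", 0.001), ("chr1", 20, "A", "C", 0.001),
            ("chr1", 30, "A", "C", 0.004), ("chr1", 40, "A", "C", 0.2),
        ])
        bg = build_gc_background(genome, panel, bin_size=500,
                                 min_bins_per_group=1)
        assert bg.lookup(50.0) == pytest.approx(0.75)

    def test_all_gc_bin_is_group_100(self):
        assert bin_gc_percent("GC" * 100) == 100
        assert bin_gc_percent("AT" * 100) == 0

    def test_nearest_lookup_ties_break_low(self):
        bg = GCBackground(bin_size=500, groups={
            45: (100, 30, 70), 50: (100, 60, 40),
        })
        assert bg.lookup(47.2) == pytest.approx(0.30)   # nearest is 45
        assert bg.lookup(47.5) == pytest.approx(0.30)   # tie -> lower GC
        assert bg.lookup(49.0) == pytest.approx(0.60)

    def test_small_group_merging_deterministic(self):
        groups = {40: [5, 1, 1], 45: [100, 10, 10], 60: [4, 0, 2]}
        merged = _merge_small_groups(groups, min_bins=50)
        assert set(merged) == {45}
        assert merged[45] == [109, 11, 13]

    def test_zero_variant_group_excluded_with_warning(self):
        genome = {"chr1": "AT" * 500 + "GC" * 500}  # groups 0 and 100
        panel = self.panel([("chr1", 10, "A", "C", 0.001),
                            ("chr1", 20, "T", "C", 0.2)])
        with pytest.warns(UserWarning, match="excluded from lookup"):
            bg = build_gc_background(genome, panel, 500, min_bins_per_group=1)
        # only the AT group holds variants; any lookup resolves to it
        assert bg.lookup(90.0) == pytest.approx(0.5)

    def test_order_invariance(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}
        rows = [("chr1", int(p), "A", "C",
                 0.001 if rng.random() < 0.3 else 0.2)
                for p in rng.choice(20_000, 500, replace=False)]
        bg1 = build_gc_background(genome, self.panel(rows), 500, 5)
        bg2 = build_gc_background(genome, self.panel(rows[::-1]), 500, 5)
        assert bg1.groups == bg2.groups


class TestVariantPanel:
    def test_validation(self):
        with pytest.raises(ValueError, match="daf"):
            VariantPanel(pd.DataFrame(
                [("chr1", 1, "A", "C", 1.5)],
                columns=["chrom", "pos0", "ref", "alt", "daf"],
            ))
        with pytest.raises(ValueError, match="ref"):
            VariantPanel(pd.DataFrame(
                [("chr1", 1, "A", "A", 0.1)],
                columns=["chrom", "pos0", "ref", "alt", "daf"],
            ))

    def test_vcf_round_trip_skips_indels(self, tmp_path):
        vcf = tmp_path / "p.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tG\t.\t.\tAF=0.001\n"
            "chr1\t200\t.\tAT\tA\t.\t.\tAF=0.2\n"
            "chr1\t300\t.\tC\tT\t.\t.\tAF=0.3\n"
        )
        with pytest.warns(UserWarning, match="skipped 1"):
            panel = VariantPanel.from_vcf(vcf)
        assert len(panel) == 2
        assert panel.table.pos0.tolist() == [99, 299]  # 1-based -> 0-based
        assert panel.is_rare.tolist() == [True, False]
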