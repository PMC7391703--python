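"""Entropy weights, GC-adjusted enrichment, hub table, sigmoid, structure."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rbpscore.context import GCBackground, VariantPanel
from rbpscore.conservation import (
    GerpTransform, RareFractionStats, build_conservation_table,
    build_hub_score_table, coverage_entropy, entropy_weight,
    gc_adjusted_enrichment, gerp_component, rare_fraction,
    structure_component, ValueTrack,
)
from rbpscore.intervals import IntervalSet


class TestEntropyWeight:
    @pytest.mark.parametrize("f,expected", [
        (0.0, 1.0),
        (1.0, 1.0),
        (0.5, 0.0),
        # 1 + 0.25*log2(0.25) + 0.75*log2(0.75), evaluated independently
        (0.25, 1.0 + 0.25 * math.log2(0.25) + 0.75 * math.log2(0.75)),
    ])
    def test_closed_form(self, f, expected):
        assert entropy_weight(f) == pytest.approx(expected, abs=1e-15)
        assert entropy_weight(0.25) == pytest.approx(0.18872, abs=5e-6)

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(0.0, 1.0, allow_nan=False))
    def test_symmetric_and_bounded(self, f):
        s = entropy_weight(f)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(entropy_weight(1.0 - f), abs=1e-12)

    def test_coverage_entropy_contract(self):
        assert coverage_entropy(0, 10) == 1.0
        assert coverage_entropy(5, 10) == 0.0
        with pytest.raises(ValueError):
            coverage_entropy(0, 0)
        with pytest.raises(ValueError):
            coverage_entropy(11, 10)


def make_panel(rows):
    return VariantPanel(pd.DataFrame(
        rows, columns=["chrom", "pos0", "ref", "alt", "daf"]
    ))


class TestRareFraction:
    def test_direct_counting(self):
        panel = make_panel([
            ("chr1", 5, "A", "C", 0.001), ("chr1", 6, "A", "C", 0.002),
            ("chr1", 7, "A", "C", 0.005), ("chr1", 8, "A", "C", 0.3),
            ("chr1", 99, "A", "C", 0.001),  # outside
        ])
        regions = IntervalSet.from_intervals([("chr1", 0, 50)])
        stats = rare_fraction(panel, regions)
        assert (stats.n_r, stats.n_c) == (3, 1)
        assert stats.rho == pytest.approx(0.75)

    def test_all_rare(self):
        panel = make_panel([("chr1", 5, "A", "C", 0.001),
                            ("chr1", 6, "A", "C", 0.004)])
        stats = rare_fraction(panel, IntervalSet.from_intervals(
            [("chr1", 0, 50)]))
        assert stats.rho == 1.0

    def test_empty_region_set_flagged_undefined(self):
        panel = make_panel([("chr1", 500, "A", "C", 0.001)])
        stats = rare_fraction(panel, IntervalSet.from_intervals(
            [("chr1", 0, 50)]))
        assert not stats.defined
        assert math.isnan(stats.rho)
        with pytest.raises(ValueError):
            gc_adjusted_enrichment(
                stats, GCBackground(500, {50: (10, 5, 5)})
            )


class TestGCAdjustedEnrichment:
    def test_identity_and_division(self):
        bg = GCBackground(500, {50: (100, 40, 60)})  # rho_b = 0.40
        assert gc_adjusted_enrichment(
            RareFractionStats(40, 60, 50.0), bg) == pytest.approx(1.0)
        assert gc_adjusted_enrichment(
            RareFractionStats(45, 55, 50.0), bg) == pytest.approx(1.125)


class TestConservationTable:
    def test_single_rbp_closed_form(self, worked_ctx, worked):
        """Hand-composed rho_adj * S_f for the documented toy context."""
        t = worked_ctx.cons_table.table.set_index(["rbp_id", "partition"])
        row = t.loc[("RBPB", "noncoding")]
        s_f = 1 + 0.3 * math.log2(0.3) + 0.7 * math.log2(0.7)
        assert row["score"] == pytest.approx(((4 / 6) / 0.6) * s_f, rel=1e-12)
        row = t.loc[("RBPA", "coding")]
        s_f = 1 + 0.2 * math.log2(0.2) + 0.8 * math.log2(0.8)
        assert row["score"] == pytest.approx((0.75 / 0.6) * s_f, rel=1e-12)

    def test_query_takes_max_over_binding_rbps(self, worked_ctx):
        score, rbp = worked_ctx.cons_table.score_at("chr1", 1120)
        t = worked_ctx.cons_table.table.set_index(["rbp_id", "partition"])
        assert rbp == "RBPB"
        assert score == pytest.approx(
            max(t.loc[("RBPA", "noncoding"), "score"],
                t.loc[("RBPB", "noncoding"), "score"])
        )

    def test_query_outside_peaks_is_zero(self, worked_ctx):
        assert worked_ctx.cons_table.score_at("chr1", 5000) == (0.0, None)


class TestHubScoreTable:
    def test_structural_contract(self, small_ctx):
        """0 below hot, plateau at/above ultra equal to max smoothed hot."""
        for part, tab in small_ctx.hub_table.partitions.items():
            df = tab.table
            below = df[df["H"] < tab.h_hot]
            assert (below["component"] == 0.0).all()
            above = df[df["H"] >= tab.h_ultra]
            assert np.allclose(above["component"], tab.plateau)
            hot = df[(df["H"] >= tab.h_hot) & (df["H"] < tab.h_ultra)]
            if len(hot):
                assert tab.plateau == pytest.approx(hot["component"].max())
            assert (df["component"] >= 0).all()

    def test_thresholds_are_base_weighted_tail_quantiles(self, small_ctx):
        for part, tab in small_ctx.hub_table.partitions.items():
            df = tab.table.sort_values("H")
            total = df["n_bases"].sum()
            tail = {
                int(h): df.loc[df["H"] >= h, "n_bases"].sum() / total
                for h in df["H"]
            }
            qualifying = [h for h, t in tail.items() if t <= 0.05]
            if qualifying:
                assert tab.h_hot == min(qualifying)

    def test_degenerate_single_stratum(self):
        """All positions share one H: hot == ultra-hot, plateau only."""
        from rbpscore.context import (
            RBPPeakCollection, build_hub_track, partition_by_coding,
        )
        genome = {"chr1": "ACGT" * 500}
        peaks = pd.DataFrame([("chr1", 100, 300, "+", 1000.0)],
                             columns=["chrom", "start", "end", "strand",
                                      "score"])
        colls = {"R": RBPPeakCollection("R", ("X",), peaks)}
        cds = IntervalSet.from_intervals([("chr1", 1500, 1600)])
        part = partition_by_coding(colls, cds)
        hub = build_hub_track(colls)
        panel = make_panel([("chr1", 150, "A", "C", 0.001),
                            ("chr1", 160, "A", "C", 0.3)])
        bg = GCBackground(500, {50: (4, 1, 1)})
        with pytest.warns(UserWarning):
            table = build_hub_score_table(hub, part, panel, bg, genome)
        tab = table.partitions["noncoding"]
        assert tab.h_hot == tab.h_ultra == 1
        assert table.score_at("chr1", 150)[0] == pytest.approx(tab.plateau)


class TestGerp:
    def test_midpoint_exact(self):
        tf = GerpTransform()
        assert tf(2.0) == pytest.approx(0.5, abs=1e-15)

    def test_default_steepness_anchors(self):
        tf = GerpTransform()
        assert tf(3.0) == pytest.approx(0.95, abs=1e-12)
        assert tf(1.0) == pytest.approx(0.05, abs=1e-12)
        assert tf(-5.0) == pytest.approx(1.0 / (1.0 + 19.0 ** 7), rel=1e-9)

    def test_strictly_increasing(self):
        tf = GerpTransform()
        xs = np.linspace(-10, 10, 201)
        ys = [tf(x) for x in xs]
        assert all(b > a for a, b in zip(ys, ys[1:]))
        assert all(0.0 < y < 1.0 for y in ys)

    def test_missing_value_scores_zero_with_flag(self):
        tf = GerpTransform()
        assert gerp_component(None, tf) == (0.0, True)
        assert gerp_component(float("nan"), tf) == (0.0, True)
        score, missing = gerp_component(2.0, tf)
        assert (score, missing) == (0.5, False)

    def test_value_track_step_lookup(self):
        track = ValueTrack({"chr1": (
            np.array([100, 300]), np.array([200, 400]), np.array([1.5, -2.0]),
        )})
        assert track.value_at("chr1", 150) == 1.5
        assert track.value_at("chr1", 250) is None
        assert track.value_at("chr1", 399) == -2.0
        assert track.value_at("chr2", 0) is None


class TestStructure:
    def test_indicator_half_open(self):
        regions = IntervalSet.from_intervals([("chr1", 100, 200)])
        assert structure_component("chr1", 150, regions) == 1
        assert structure_component("chr1", 99, regions) == 0
        assert structure_component("chr1", 200, regions) == 0  # end excluded
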