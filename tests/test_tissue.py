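"""Regulatory potential, burden testing, tissue category scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rbpscore.kd import PeakGeneLink
from rbpscore.simulate import sample_burden_world, sample_connectivity_de
from rbpscore.tissue import (
    binomial_burden_pvalue, burdened_peaks, key_regulators,
    peak_burden_test, regulatory_potential, tissue_component,
)


class TestRegulatoryPotential:
    def test_flat_response_gives_zero_slope(self):
        x = np.array([1, 1, 0, 0, 0])
        y = np.array([1, 1, 1, 1, 1])
        res = regulatory_potential(x, y)
        assert res.beta1 == pytest.approx(0.0)

    def test_slope_equals_group_mean_difference(self, rng):
        """Binary-covariate OLS identity, 50 random draws."""
        for _ in range(50):
            n = int(rng.integers(20, 200))
            x = (rng.random(n) < 0.4).astype(int)
            if x.sum() < 2 or (1 - x).sum() < 2:
                continue
            y = (rng.random(n) < 0.3).astype(int)
            res = regulatory_potential(x, y)
            expected = y[x == 1].mean() - y[x == 0].mean()
            assert res.beta1 == pytest.approx(expected, abs=1e-12)
            assert res.potential == abs(res.beta1)

    def test_planted_rates_example(self):
        x = np.array([1] * 10 + [0] * 10)
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0,
                      1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        res = regulatory_potential(x, y)
        assert res.beta1 == pytest.approx(0.30 - 0.10)

    def test_degenerate_strata_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = regulatory_potential(np.array([1, 0, 0, 0]),
                                       np.array([1, 0, 1, 0]), "RBPZ")
        assert not res.defined
        assert key_regulators([res]) == set()

    def test_key_regulator_selection(self):
        x, y = sample_connectivity_de(seed=1, n_genes=2000)
        strong = regulatory_potential(x, y, "strong")
        rng = np.random.default_rng(2)
        null = regulatory_potential(
            (rng.random(2000) < 0.3).astype(int),
            (rng.random(2000) < 0.2).astype(int), "null",
        )
        keys = key_regulators([strong, null])
        assert "strong" in keys


class TestBinomialBurden:
    def test_zero_count_conventions(self):
        assert binomial_burden_pvalue(0, 10, 0.001) == 1.0
        assert binomial_burden_pvalue(0, 0, 0.001) == 1.0

    def test_exact_tail_example(self):
        """n=10, p0=0.001, k=2 against an explicit tail sum."""
        p = binomial_burden_pvalue(2, 10, 0.001)
        exact = sum(
            sps.binom.pmf(k, 10, 0.001) for k in range(2, 11)
        )
        assert p == pytest.approx(exact, rel=1e-12)
        assert p == pytest.approx(4.4762e-5, rel=1e-4)

    def test_full_count_closed_form(self):
        assert binomial_burden_pvalue(5, 5, 0.01) == pytest.approx(0.01 ** 5)

    def test_invalid_p0(self):
        with pytest.raises(ValueError):
            binomial_burden_pvalue(1, 10, 0.0)


def reference_bh(pvals):
    """Independent step-up BH implementation."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


class TestPeakBurdenTest:
    def test_counts_and_bh_against_reference(self):
        colls, somatic, _ = sample_burden_world(
            seed=5, n_peaks=50, n_burdened=5
        )
        results = peak_burden_test(colls, somatic)
        assert len(results) == 50
        pos = somatic["pos0"].to_numpy()
        for r in results[:10]:
            assert r.k == int(((pos >= r.start) & (pos < r.end)).sum())
            w0 = ((r.start + r.end) // 2 // 1_000_000) * 1_000_000
            assert r.n == int(((pos >= w0) & (pos < w0 + 1_000_000)).sum())
            assert 0 <= r.k <= r.n
        qs = np.array([r.q_value for r in results])
        assert np.allclose(qs, reference_bh([r.p_value for r in results]))

    def test_empty_window_gives_p_one(self):
        colls, _, _ = sample_burden_world(seed=6, n_peaks=5)
        somatic = pd.DataFrame({"chrom": ["chrZ"], "pos0": [100]})
        results = peak_burden_test(colls, somatic)
        assert all(r.p_value == 1.0 for r in results)

    def test_strong_planted_burden_detected(self):
        """A 400x local excess (expected ~4 hits per 200-bp peak) is
        flagged in most planted peaks with few false positives."""
        colls, somatic, burd = sample_burden_world(
            seed=7, n_peaks=100, n_burdened=10, multiplier=400.0,
        )
        results = peak_burden_test(colls, somatic)
        detected = {r.key for r in results if r.q_value < 0.05}
        planted = {results[i].key for i in burd}
        assert detected == burdened_peaks(results)
        assert len(detected & planted) >= 7
        assert len(detected - planted) <= 2


class TestTissueComponent:
    links = [PeakGeneLink("R1", "chr1", 100, 200, "g1"),
             PeakGeneLink("R2", "chr1", 150, 250, "g2")]
    peaks = [("R1", "chr1", 100, 200), ("R2", "chr1", 150, 250)]

    def test_all_three_categories(self):
        score, cats = tissue_component(
            "chr1", 160, ["R1", "R2"], self.peaks, self.links,
            key_rbps={"R1"}, burdened={("R2", "chr1", 150, 250)},
            key_genes={"g1"},
        )
        assert score == 3
        assert cats == {"key_rbp": 1, "burden": 1, "key_gene": 1}

    def test_none_active(self):
        score, _ = tissue_component(
            "chr1", 160, ["R1"], self.peaks[:1], self.links,
            set(), set(), set(),
        )
        assert score == 0

    def test_category_level_not_per_rbp(self):
        """Two key RBPs at one variant still add only one point."""
        score, cats = tissue_component(
            "chr1", 160, ["R1", "R2"], self.peaks, self.links,
            key_rbps={"R1", "R2"}, burdened=set(), key_genes=set(),
        )
        assert score == 1
        assert cats["key_rbp"] == 1
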