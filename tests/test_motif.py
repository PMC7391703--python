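"""PWM match p-values (DP vs enumeration), disruption scores, CDF."""

import itertools
import math

import numpy as np
import pytest

from rbpscore.motif import (
    BASES, DscoreBackgroundCDF, PWM, disruption_score, dscore_from_pvalues,
    motif_component, parse_meme, parse_pwm_tsv, pwm_match_pvalue,
    reverse_complement, write_meme,
)


def random_pwm(rng, length, skew=0.0, background=None):
    probs = rng.dirichlet(np.ones(4) * 0.8, size=length)
    bg = background if background is not None else np.full(4, 0.25)
    return PWM(motif_id=f"m{length}", probs=probs, rbp_id="R",
               background=bg)


def enumeration_pvalue(pwm: PWM, int_score: int) -> float:
    """Independent oracle: sum background probabilities of every word of
    length L whose (grid) score reaches the threshold."""
    L = len(pwm)
    total = 0.0
    for word in itertools.product(range(4), repeat=L):
        s = sum(int(pwm._int_scores[i, b]) for i, b in enumerate(word))
        if s >= int_score:
            total += float(np.prod([pwm.background[b] for b in word]))
    return total


@pytest.mark.parametrize("length", [3, 4, 5, 6])
@pytest.mark.parametrize("bg", [
    np.array([0.25, 0.25, 0.25, 0.25]),
    np.array([0.4, 0.1, 0.1, 0.4]),
])
def test_dp_pvalue_equals_enumeration(length, bg):
    rng = np.random.default_rng(100 + length)
    pwm = random_pwm(rng, length, background=bg)
    # check the whole achievable range, plus both extremes
    mins = int(pwm._int_scores.min(axis=1).sum())
    maxs = int(pwm._int_scores.max(axis=1).sum())
    probe = sorted(set(
        [mins, maxs, maxs + 1]
        + list(rng.integers(mins, maxs + 1, size=25))
    ))
    for t in probe:
        assert pwm.pvalue_of_int_score(t) == pytest.approx(
            enumeration_pvalue(pwm, t), rel=1e-10, abs=1e-300
        )
    assert pwm.pvalue_of_int_score(mins) == pytest.approx(1.0)
    assert pwm.pvalue_of_int_score(maxs + 1) == 0.0


def test_best_word_pvalue_is_tie_mass():
    """Shortest allowed motif: p of the best trinucleotide equals the
    background mass of all words tied at or above its score (enumeration
    over the 64 trinucleotides)."""
    rng = np.random.default_rng(7)
    pwm = random_pwm(rng, 3)
    best_word = pwm.consensus
    s = pwm.window_int_score(best_word)
    expected = enumeration_pvalue(pwm, s)
    scan = pwm_match_pvalue(pwm, best_word)
    assert scan.pvalue == pytest.approx(expected, rel=1e-12)


class TestScan:
    def test_window_shorter_than_motif_errors(self):
        rng = np.random.default_rng(1)
        pwm = random_pwm(rng, 5)
        with pytest.raises(ValueError, match="shorter"):
            pwm_match_pvalue(pwm, "ACG")

    def test_ambiguous_bases_mask_offsets(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(rng, 4)
        scan = pwm_match_pvalue(pwm, "NNNN")
        assert not scan.hit
        scan = pwm_match_pvalue(pwm, "NACGTN")
        assert scan.hit and scan.offset == 1

    def test_both_strands_takes_better(self):
        consensus = "AACG"  # not its own reverse complement
        probs = np.full((4, 4), 0.04)
        for i, b in enumerate(consensus):
            probs[i, BASES.index(b)] = 0.88
        pwm = PWM(motif_id="aacg", probs=probs, rbp_id="R")
        fwd = pwm_match_pvalue(pwm, consensus)
        rc = pwm_match_pvalue(pwm, reverse_complement(consensus),
                              both_strands=True)
        assert rc.strand == "-"
        assert rc.int_score == fwd.int_score


class TestDisruption:
    def test_closed_form(self):
        assert dscore_from_pvalues(1e-4, 1e-2) == pytest.approx(20.0)
        assert dscore_from_pvalues(0.5, 0.5) == 0.0
        with pytest.raises(ValueError):
            dscore_from_pvalues(0.0, 0.5)

    def test_antisymmetry_on_random_triples(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        while n_checked < 500:
            L = int(rng.integers(3, 7))
            pwm = random_pwm(rng, L)
            w = "".join(rng.choice(list(BASES), size=L + 4))
            pos = int(rng.integers(0, len(w)))
            alt = rng.choice([b for b in BASES if b != w[pos]])
            w_alt = w[:pos] + alt + w[pos + 1:]
            d1, pr1, pa1 = disruption_score(pwm, w, w_alt)
            d2, pr2, pa2 = disruption_score(pwm, w_alt, w)
            assert d1 == pytest.approx(-d2, abs=1e-12)
            assert (pr1, pa1) == (pa2, pr2)
            n_checked += 1

    def test_window_validation(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, 4)
        with pytest.raises(ValueError, match="equal length"):
            disruption_score(pwm, "ACGTA", "ACGT")
        with pytest.raises(ValueError, match="exactly the variant base"):
            disruption_score(pwm, "ACGT", "TGCA")


class TestBackgroundCDF:
    def test_counting_oracle(self):
        cdf = DscoreBackgroundCDF([1.0, 2.0, 5.0, 9.0])
        assert cdf.query(3.0) == pytest.approx(0.5)
        assert cdf.query(0.0) == pytest.approx(1.0)
        assert cdf.query(9.0) == 0.0        # strictly greater
        assert cdf.query(100.0) == 0.0

    def test_gate_failures_never_exceed_queries(self):
        cdf = DscoreBackgroundCDF([-math.inf, -math.inf, 4.0, 8.0])
        assert cdf.query(-1e9) == pytest.approx(0.5)
        assert cdf.query(5.0) == pytest.approx(0.25)

    def test_empty_background_errors(self):
        with pytest.raises(ValueError, match="empty"):
            DscoreBackgroundCDF([])


class TestMotifComponent:
    def cdf(self):
        return DscoreBackgroundCDF([-math.inf] * 3 + [1.0])

    def test_below_threshold_is_zero(self):
        assert motif_component(2.9, self.cdf(), s_popcons=1.0) == 0.0
        assert motif_component(None, self.cdf(), s_popcons=1.0) == 0.0

    def test_entropy_limit_equals_popcons(self):
        # no background variant exceeds D -> f = 0 -> entropy weight 1
        assert motif_component(50.0, self.cdf(), s_popcons=0.7) == \
            pytest.approx(0.7)

    def test_quarter_fraction_closed_form(self):
        cdf = DscoreBackgroundCDF([1.0, 10.0, -math.inf, -math.inf])
        s = 1 + 0.25 * math.log2(0.25) + 0.75 * math.log2(0.75)
        assert motif_component(5.0, cdf, s_popcons=1.2) == \
            pytest.approx(s * 1.2, rel=1e-12)

    def test_zero_popcons_zeroes_component(self):
        assert motif_component(50.0, self.cdf(), s_popcons=0.0) == 0.0


class TestPWMIO:
    def test_meme_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        pwms = [random_pwm(rng, 5), random_pwm(rng, 6)]
        pwms[1].motif_id = "m6b"
        path = tmp_path / "m.meme"
        write_meme(pwms, path)
        back = parse_meme(path, pseudocount=0.0)
        assert [p.motif_id for p in back] == ["m5", "m6b"]
        assert np.allclose(back[0].probs, pwms[0].probs, atol=1e-5)

    def test_tsv_dialect(self, tmp_path):
        path = tmp_path / "RBPQ_motif.tsv"
        path.write_text("A\tC\tG\tT\n0.7\t0.1\t0.1\t0.1\n"
                        "0.1\t0.7\t0.1\t0.1\n0.1\t0.1\t0.7\t0.1\n")
        pwm = parse_pwm_tsv(path)
        assert pwm.motif_id == "RBPQ_motif"
        assert pwm.rbp_id == "RBPQ"
        assert len(pwm) == 3
        assert pwm.consensus == "ACG"

    def test_pwm_validation(self):
        with pytest.raises(ValueError, match=">= 3"):
            PWM(motif_id="x", probs=np.full((2, 4), 0.25))
        with pytest.raises(ValueError, match="\\(L, 4\\)"):
            PWM(motif_id="x", probs=np.full((4, 3), 1 / 3))
        pwm = PWM(motif_id="x", probs=np.full((4, 4), 0.25))
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)
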