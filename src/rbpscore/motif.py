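"""PWM match significance and motif-disruption scoring.

A match p-value is the probability, under an i.i.d. background, that a
single window scores at least as high as the observed best window. It is
computed exactly by dynamic programming over the discretized per-column
log-likelihood-ratio scores (the classic lattice-convolution approach):
column scores are rounded to a grid of 1/1000 of the total score range,
the score distribution of a random window is built by convolving the
four-spike column distributions, and the p-value is a suffix sum. The
observed window's score lives on the same grid, so the DP tail equals a
brute-force enumeration over all 4^L windows exactly.

A variant's disruption score compares the best-match p-values of the
reference and alternate windows::

    D = -10 * log10(p_ref / p_alt)

positive when the alternate allele weakens the match. D > 3 with a
significant reference match (p_ref <= 5e-4) is called disruptive; the
disruption's rarity among panel variants is converted to an entropy
weight and multiplied by the population-conservation score.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .conservation import entropy_weight

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# PWM

@dataclass
class PWM:
    """Position probability matrix with a background model.

    ``probs`` is (L, 4) over A,C,G,T; a pseudocount is added to every
    cell and columns renormalized on construction. Scores are log2
    likelihood ratios against ``background``.
    """

    motif_id: str
    probs: np.ndarray
    rbp_id: str = ""
    source: str = "invitro"
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.001
    granularity: int = 1000

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if p.shape[0] < 3:
            raise ValueError("motif length must be >= 3")
        if (p < 0).any():
            raise ValueError("probabilities must be nonnegative")
        p = p + self.pseudocount
        self.probs = p / p.sum(axis=1, keepdims=True)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any():
            raise ValueError("background must be 4 positive frequencies")
        self.background = bg / bg.sum()
        self._llr = np.log2(self.probs / self.background)
        # common integer grid for the whole matrix
        span = float(self._llr.max(axis=1).sum() - self._llr.min(axis=1).sum())
        self._delta = span / self.granularity if span > 0 else 1.0
        self._int_scores = np.rint(self._llr / self._delta).astype(np.int64)
        self._tail: Optional[np.ndarray] = None
        self._tail_offset = 0

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    # -- exact score distribution ------------------------------------------

    def _build_tail(self) -> None:
        mins = self._int_scores.min(axis=1)
        dist = np.array([1.0])
        offset = 0  # dist[i] = P(sum == offset + i)
        for col, lo in zip(self._int_scores, mins):
            span = int(col.max() - lo)
            new = np.zeros(len(dist) + span)
            for b in range(4):
                sh = int(col[b] - lo)
                new[sh:sh + len(dist)] += dist * self.background[b]
            dist = new
            offset += int(lo)
        self._tail = np.cumsum(dist[::-1])[::-1]  # P(sum >= offset + i)
        self._tail_offset = offset

    def pvalue_of_int_score(self, score: int) -> float:
        """P(random window int-score >= score) under the background."""
        if self._tail is None:
            self._build_tail()
        i = score - self._tail_offset
        if i < 0:
            return 1.0
        if i >= len(self._tail):
            return 0.0
        return float(self._tail[i])

    def window_int_score(self, window: str) -> Optional[int]:
        """Integer score of one L-length window; None if it contains N."""
        if len(window) != len(self):
            raise ValueError("window length must equal motif length")
        total = 0
        for i, base in enumerate(window.upper()):
            j = BASE_INDEX.get(base)
            if j is None:
                return None
            total += int(self._int_scores[i, j])
        return total


@dataclass
class MotifScan:
    """Best match of one PWM in a sequence window."""

    hit: bool
    score: float = float("nan")  # log2 LLR on the discretized grid
    pvalue: float = float("nan")
    offset: int = -1
    strand: str = "+"
    int_score: int = 0


def pwm_match_pvalue(
    pwm: PWM, sequence: str, both_strands: bool = False
) -> MotifScan:
    """Best-offset match score and its exact p-value.

    Offsets containing ambiguous bases are skipped; if every offset is
    masked the scan is flagged as no-hit. With ``both_strands`` the
    reverse complement is scanned too and the better strand kept.
    """
    sequence = sequence.upper()
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError(
            f"window of length {len(sequence)} shorter than motif ({L})"
        )
    best: Optional[Tuple[int, int, str]] = None  # (int_score, offset, strand)
    strands = [("+", sequence)]
    if both_strands:
        strands.append(("-", reverse_complement(sequence)))
    for strand, seq in strands:
        for off in range(len(seq) - L + 1):
            s = pwm.window_int_score(seq[off:off + L])
            if s is None:
                continue
            if best is None or s > best[0]:
                best = (s, off, strand)
    if best is None:
        return MotifScan(hit=False)
    int_score, off, strand = best
    return MotifScan(
        hit=True,
        score=int_score * pwm._delta,
        pvalue=pwm.pvalue_of_int_score(int_score),
        offset=off,
        strand=strand,
        int_score=int_score,
    )


def dscore_from_pvalues(p_ref: float, p_alt: float) -> float:
    """``D = -10*log10(p_ref / p_alt)`` on the decibel scale."""
    if not (0.0 < p_ref <= 1.0 and 0.0 < p_alt <= 1.0):
        raise ValueError("match p-values must lie in (0, 1]")
    return -10.0 * math.log10(p_ref / p_alt)


def disruption_score(
    pwm: PWM, ref_window: str, alt_window: str, both_strands: bool = False
) -> Tuple[float, float, float]:
    """(D, p_ref, p_alt): ``D = -10*log10(p_ref / p_alt)``.

    Windows must be equal length and differ at a single base.
    """
    if len(ref_window) != len(alt_window):
        raise ValueError("ref and alt windows must have equal length")
    diffs = sum(a != b for a, b in zip(ref_window.upper(), alt_window.upper()))
    if diffs > 1:
        raise ValueError("windows must differ at exactly the variant base")
    ref = pwm_match_pvalue(pwm, ref_window, both_strands)
    alt = pwm_match_pvalue(pwm, alt_window, both_strands)
    if not (ref.hit and alt.hit):
        raise ValueError("no scorable offset in ref or alt window")
    d = dscore_from_pvalues(ref.pvalue, alt.pvalue)
    return d, ref.pvalue, alt.pvalue


# ---------------------------------------------------------------------------
# per-variant disruption over the binding RBPs

@dataclass
class VariantDisruption:
    """Best (gated) disruption per binding RBP at one variant."""

    per_rbp: Dict[str, float]          # rbp -> best gated d_score
    max_d: Optional[float]             # overall max, None if nothing gated in
    best_pwm: Optional[str] = None


def _passes_gate(p_ref: float, gate: float, direction: str) -> bool:
    return p_ref <= gate if direction == "le" else p_ref >= gate


def variant_disruption(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    binding: Dict[str, str],
    pwms_by_rbp: Dict[str, List[PWM]],
    genome,
    p_ref_gate: float = 5e-4,
    gate_direction: str = "le",
) -> VariantDisruption:
    """Score motif disruption at a variant for each binding RBP.

    ``binding`` maps each RBP bound at the position to its peak strand
    ('+'/'-' scans that strand's sequence, '.' scans both). The scan
    window extends motif-length − 1 bases to each side of the variant so
    every offset covering it is scored. The per-RBP score is the max D
    over that RBP's PWMs whose reference match passes the significance
    gate.
    """
    per_rbp: Dict[str, float] = {}
    best_pwm = None
    best_d = None
    for rbp, strand in binding.items():
        for pwm in pwms_by_rbp.get(rbp, []):
            L = len(pwm)
            lo = max(0, pos - (L - 1))
            hi = pos + L
            window = str(genome[chrom][lo:hi]).upper()
            centre = pos - lo
            if len(window) < L:
                continue
            genome_base = window[centre]
            if genome_base != ref.upper():
                warnings.warn(
                    f"{chrom}:{pos}: reference allele {ref} does not match "
                    f"genome base {genome_base}; using the stated allele"
                )
            ref_w = window[:centre] + ref.upper() + window[centre + 1:]
            alt_w = window[:centre] + alt.upper() + window[centre + 1:]
            if strand == "-":
                ref_w, alt_w = reverse_complement(ref_w), reverse_complement(alt_w)
            both = strand == "."
            try:
                d, p_ref, _ = disruption_score(pwm, ref_w, alt_w, both)
            except ValueError:
                continue
            if not _passes_gate(p_ref, p_ref_gate, gate_direction):
                continue
            if rbp not in per_rbp or d > per_rbp[rbp]:
                per_rbp[rbp] = d
            if best_d is None or d > best_d:
                best_d, best_pwm = d, pwm.motif_id
    return VariantDisruption(per_rbp=per_rbp, max_d=best_d, best_pwm=best_pwm)


# ---------------------------------------------------------------------------
# background CDF of disruption scores

class DscoreBackgroundCDF:
    """Right-continuous upper-tail CDF of panel-variant disruption scores.

    ``query(D)`` returns the fraction of recorded regulome panel variants
    whose score strictly exceeds D. Variants failing the reference gate
    are recorded as -inf so they never exceed any query.
    """

    def __init__(self, scores: Sequence[float]):
        arr = np.asarray(list(scores), dtype=float)
        if len(arr) == 0:
            raise ValueError(
                "empty disruption-score background; the panel contributes "
                "no regulome variants"
            )
        self.scores = np.sort(arr)

    def __len__(self) -> int:
        return len(self.scores)

    def query(self, d: float) -> float:
        n_gt = len(self.scores) - np.searchsorted(self.scores, d, side="right")
        return float(n_gt) / len(self.scores)


def build_dscore_cdf(
    panel_variants,
    collections,
    pwms_by_rbp: Dict[str, List[PWM]],
    genome,
    p_ref_gate: float = 5e-4,
    gate_direction: str = "le",
) -> DscoreBackgroundCDF:
    """Record every regulome panel variant's max gated disruption score.

    ``panel_variants`` is an iterable of (chrom, pos0, ref, alt) already
    restricted to the regulome; ``collections`` maps rbp -> peak
    collection (used for binding and strand).
    """
    scores = []
    for chrom, pos, ref, alt in panel_variants:
        binding = binding_rbps_at(collections, chrom, pos)
        if not binding:
            continue
        dis = variant_disruption(
            chrom, pos, ref, alt, binding, pwms_by_rbp, genome,
            p_ref_gate, gate_direction,
        )
        scores.append(dis.max_d if dis.max_d is not None else -math.inf)
    return DscoreBackgroundCDF(scores)


def binding_rbps_at(collections, chrom: str, pos: int) -> Dict[str, str]:
    """RBPs whose footprint covers a position, with the covering strand.

    If peaks on both strands of one RBP cover the position the strand is
    '.' (scan both).
    """
    out: Dict[str, str] = {}
    for rbp, coll in collections.items():
        hits = coll.peaks_at(chrom, pos)
        if hits.empty:
            continue
        strands = set(hits["strand"])
        out[rbp] = strands.pop() if len(strands) == 1 else "."
    return out


def motif_component(
    max_d: Optional[float],
    cdf: DscoreBackgroundCDF,
    s_popcons: float,
    d_threshold: float = 3.0,
) -> float:
    """Entropy-weighted disruption component.

    0 unless the max gated disruption exceeds the threshold; otherwise
    the rarity entropy ``1 + f*log2 f + (1-f)*log2(1-f)`` of
    ``f = P(panel D > max_d)`` multiplied by the population-conservation
    score at the variant.
    """
    if max_d is None or max_d <= d_threshold:
        return 0.0
    f = cdf.query(max_d)
    return entropy_weight(f) * s_popcons


# ---------------------------------------------------------------------------
# PWM parsing

def parse_meme(
    path: str | Path, default_rbp: str | None = None,
    pseudocount: float = 0.001, granularity: int = 1000,
) -> List[PWM]:
    """Parse a MEME-minimal motif file into PWMs.

    The RBP id defaults to the motif name's prefix before the first
    underscore (the convention used by this package's fixtures); override
    via ``default_rbp`` or rename afterwards.
    """
    text = Path(path).read_text()
    bg = np.full(4, 0.25)
    m = re.search(
        r"Background letter frequencies.*?\n([ACGT0-9.\seE+-]+)\n", text
    )
    if m:
        toks = m.group(1).split()
        try:
            freq = {toks[i]: float(toks[i + 1]) for i in range(0, len(toks), 2)}
            bg = np.array([freq.get(b, 0.25) for b in BASES])
        except (ValueError, IndexError):
            pass
    pwms = []
    for mm in re.finditer(
        r"MOTIF\s+(\S+)[^\n]*\n.*?letter-probability matrix:[^\n]*\n"
        r"((?:\s*[\d.eE+-]+\s+[\d.eE+-]+\s+[\d.eE+-]+\s+[\d.eE+-]+\s*\n)+)",
        text, flags=re.S,
    ):
        name = mm.group(1)
        rows = [
            [float(x) for x in line.split()]
            for line in mm.group(2).strip().splitlines()
        ]
        rbp = default_rbp or name.split("_")[0]
        pwms.append(PWM(
            motif_id=name, probs=np.array(rows), rbp_id=rbp, background=bg,
            pseudocount=pseudocount, granularity=granularity,
        ))
    if not pwms:
        raise ValueError(f"{path}: no motifs parsed")
    return pwms


def parse_pwm_tsv(
    path: str | Path, motif_id: str | None = None,
    rbp_id: str | None = None,
) -> PWM:
    """Parse a plain 4-column (A C G T) probability TSV as one PWM."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if toks[0].upper() == "A" and len(toks) == 4:
                continue  # header row
            rows.append([float(x) for x in toks[:4]])
    mid = motif_id or Path(path).stem
    return PWM(
        motif_id=mid, probs=np.array(rows),
        rbp_id=rbp_id or mid.split("_")[0],
    )


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs in MEME-minimal format (deterministic text)."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "",
             "Background letter frequencies", ]
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    lines.append(" ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(BASES)))
    lines.append("")
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.motif_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {len(pwm)} "
            f"nsites= 20 E= 0"
        )
        for row in pwm.probs:
            lines.append(" ".join(f"{x:.6f}" for x in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")
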