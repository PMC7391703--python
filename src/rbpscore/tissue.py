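"""Tissue-specific scoring: regulatory potential, somatic burden, key genes.

Three user-supplied evidence categories each contribute a fixed +1:

* **Regulatory potential** — regress genes' binary differential-expression
  status on an RBP's binary target-connectivity vector; for a binary
  covariate the OLS slope is exactly the DE-rate difference between
  targets and non-targets, and an RBP with a significant slope is a key
  regulator.
* **Mutation burden** — each peak's somatic mutation count is tested
  against its local 1-Mbp window rate with a one-sided binomial test,
  BH-adjusted across peaks.
* **Key genes** — membership of any linked gene in the user's prior list
  or among differentially expressed genes.

The categories are indicators: two key RBPs at one variant still add 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kd import PeakGeneLink, links_at


# ---------------------------------------------------------------------------
# regulatory potential (per-RBP regression)

@dataclass
class RegulatoryPotential:
    rbp_id: str
    condition: str
    beta0: float
    beta1: float
    p_value: float
    defined: bool = True

    @property
    def potential(self) -> float:
        return abs(self.beta1)


def connectivity_vector(
    links: Sequence[PeakGeneLink], rbp_id: str, genes: Sequence[str]
) -> np.ndarray:
    """Binary vector over ``genes``: 1 iff the gene has a link to the RBP."""
    targets = {ln.gene_id for ln in links if ln.rbp_id == rbp_id}
    return np.array([1 if g in targets else 0 for g in genes], dtype=int)


def regulatory_potential(
    x: np.ndarray, y: np.ndarray, rbp_id: str = "", condition: str = "",
) -> RegulatoryPotential:
    """OLS of DE status ``y`` on binary connectivity ``x``.

    For binary x the slope equals mean(y|x=1) − mean(y|x=0); the p-value
    is the slope's two-sided t-test. Fewer than 2 genes in either
    stratum makes the fit degenerate: flagged undefined and excluded
    from the key-regulator set by the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must align over the same genes")
    n1, n0 = int((x == 1).sum()), int((x == 0).sum())
    if n1 < 2 or n0 < 2:
        warnings.warn(
            f"RBP {rbp_id or '?'}: degenerate connectivity strata "
            f"(n1={n1}, n0={n0}); regulatory potential undefined"
        )
        return RegulatoryPotential(
            rbp_id, condition, np.nan, np.nan, np.nan, defined=False
        )
    res = stats.linregress(x, y)
    return RegulatoryPotential(
        rbp_id, condition,
        beta0=float(res.intercept), beta1=float(res.slope),
        p_value=float(res.pvalue),
    )


def key_regulators(
    potentials: Sequence[RegulatoryPotential],
    p_threshold: float = 0.05,
    bh_adjust: bool = False,
) -> Set[str]:
    """RBPs with a significant slope in any condition."""
    defined = [p for p in potentials if p.defined]
    if not defined:
        return set()
    pvals = np.array([p.p_value for p in defined])
    if bh_adjust:
        sig = multipletests(pvals, method="fdr_bh")[0] & (pvals < 1)
    else:
        sig = pvals < p_threshold
    return {p.rbp_id for p, s in zip(defined, sig) if s}


# ---------------------------------------------------------------------------
# somatic-mutation burden

@dataclass
class BurdenResult:
    rbp_id: str
    chrom: str
    start: int
    end: int
    k: int            # mutations in peak
    n: int            # mutations in window
    p0: float         # peak_length / window_length
    p_value: float
    q_value: float = float("nan")

    @property
    def key(self) -> Tuple[str, str, int, int]:
        return (self.rbp_id, self.chrom, self.start, self.end)


def binomial_burden_pvalue(k: int, n: int, p0: float) -> float:
    """One-sided upper-tail binomial p: P(X >= k), X ~ Bin(n, p0).

    A window with no mutations (n = 0) gives p = 1 by convention.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    if n == 0 or k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def peak_burden_test(
    collections,
    somatic: pd.DataFrame,
    window_bp: int = 1_000_000,
    chrom_lengths: Optional[Dict[str, int]] = None,
    q_threshold: float = 0.05,
) -> List[BurdenResult]:
    """Test every peak's somatic-mutation count against its local window.

    Windows tile each chromosome from coordinate 0; a peak belongs to
    the window containing its midpoint. ``somatic`` has columns chrom,
    pos0. BH adjustment is applied across all tested peaks.
    """
    mut_by_chrom = {
        str(c): np.sort(g["pos0"].to_numpy(np.int64))
        for c, g in somatic.groupby("chrom", sort=True)
    }
    results: List[BurdenResult] = []
    for rbp in sorted(collections):
        for row in collections[rbp].peaks.itertuples():
            chrom = str(row.chrom)
            mid = (row.start + row.end) // 2
            w0 = (mid // window_bp) * window_bp
            w1 = w0 + window_bp
            if chrom_lengths and chrom in chrom_lengths:
                w1 = min(w1, chrom_lengths[chrom])
            wlen = w1 - w0
            peak_len = row.end - row.start
            p0 = min(max(peak_len / wlen, 1e-12), 1 - 1e-12)
            pos = mut_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
            n = int(np.searchsorted(pos, w1) - np.searchsorted(pos, w0))
            k = int(
                np.searchsorted(pos, row.end) - np.searchsorted(pos, row.start)
            )
            p = binomial_burden_pvalue(k, n, p0)
            results.append(BurdenResult(
                rbp, chrom, int(row.start), int(row.end), k, n, p0, p
            ))
    if results:
        qs = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def burdened_peaks(
    results: Sequence[BurdenResult], q_threshold: float = 0.05
) -> Set[Tuple[str, str, int, int]]:
    return {r.key for r in results if r.q_value < q_threshold}


# ---------------------------------------------------------------------------
# combined tissue component

def tissue_component(
    chrom: str,
    pos: int,
    binding_rbps: Sequence[str],
    containing_peaks: Sequence[Tuple[str, str, int, int]],
    links: Sequence[PeakGeneLink],
    key_rbps: Set[str],
    burdened: Set[Tuple[str, str, int, int]],
    key_genes: Set[str],
) -> Tuple[int, Dict[str, int]]:
    """Category-level tissue score in {0,..,3} plus per-category flags.

    +1 if any binding RBP is a key regulator; +1 if any containing peak
    (``(rbp, chrom, start, end)`` tuples) is burdened; +1 if any gene
    linked to a containing peak is a key gene. Multiple hits within one
    category still count once.
    """
    here = links_at(list(links), chrom, pos)
    cat = {
        "key_rbp": int(any(r in key_rbps for r in binding_rbps)),
        "burden": int(any(pk in burdened for pk in containing_peaks)),
        "key_gene": int(any(ln.gene_id in key_genes for ln in here)),
    }
    return sum(cat.values()), cat
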