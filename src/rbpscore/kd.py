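"""Peak-gene linkage and the knockdown-association component.

A peak of RBP R is linked to gene g when it overlaps any base of any of
g's transcripts (exons and introns — binding is frequently intronic). A
variant earns the +1 knockdown component when it sits in a linked peak
of R, significantly disrupts R's motif (D > 3), and depleting R changes
g's expression by at least 2.5-fold in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PeakGeneLink:
    rbp_id: str
    chrom: str
    start: int
    end: int
    gene_id: str


def link_peaks_to_genes(
    collections, transcripts: pd.DataFrame
) -> List[PeakGeneLink]:
    """One link per (rbp, peak, gene) with nonzero transcript overlap.

    ``transcripts`` needs columns chrom, start, end, gene_id (transcript
    spans, exons+introns). A peak overlapping transcripts of several
    genes links to each of them.
    """
    links: List[PeakGeneLink] = []
    tx_by_chrom = {
        str(c): g.sort_values("start")
        for c, g in transcripts.groupby("chrom", sort=True)
    }
    for rbp in sorted(collections):
        for row in collections[rbp].peaks.itertuples():
            tx = tx_by_chrom.get(str(row.chrom))
            if tx is None:
                continue
            ovl = tx[(tx["start"] < row.end) & (tx["end"] > row.start)]
            for gene in sorted(set(ovl["gene_id"])):
                links.append(PeakGeneLink(
                    rbp, str(row.chrom), int(row.start), int(row.end), gene
                ))
    return links


def links_at(
    links: List[PeakGeneLink], chrom: str, pos: int
) -> List[PeakGeneLink]:
    """Links whose peak contains the position."""
    return [
        ln for ln in links
        if ln.chrom == chrom and ln.start <= pos < ln.end
    ]


class KnockdownTable:
    """(rbp, gene) -> expression fold change after depleting the RBP."""

    def __init__(self, table: pd.DataFrame):
        fc = table["fold_change"].to_numpy(float)
        if (fc <= 0).any() or not np.isfinite(fc).all():
            raise ValueError("fold changes must be finite and positive")
        self.table = table
        self._fc: Dict[Tuple[str, str], float] = {
            (str(r.rbp_id), str(r.gene_id)): float(r.fold_change)
            for r in table.itertuples()
        }

    def fold_change(self, rbp: str, gene: str) -> Optional[float]:
        return self._fc.get((rbp, gene))

    def responds(
        self, rbp: str, gene: str, threshold: float = 2.5,
        two_sided: bool = True,
    ) -> bool:
        fc = self.fold_change(rbp, gene)
        if fc is None:
            return False
        if two_sided:
            return fc >= threshold or fc <= 1.0 / threshold
        return fc >= threshold


def kd_component(
    chrom: str,
    pos: int,
    links: List[PeakGeneLink],
    kd_table: KnockdownTable,
    d_scores: Dict[str, float],
    fc_threshold: float = 2.5,
    d_threshold: float = 3.0,
    two_sided: bool = True,
) -> int:
    """1 iff some (R, g): variant in a linked peak of R, D(R) > threshold,
    and g responds to knockdown of R; else 0."""
    for ln in links_at(links, chrom, pos):
        d = d_scores.get(ln.rbp_id)
        if d is None or d <= d_threshold:
            continue
        if kd_table.responds(ln.rbp_id, ln.gene_id, fc_threshold, two_sided):
            return 1
    return 0
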