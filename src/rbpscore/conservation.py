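"""Cross-population and cross-species conservation scoring.

The cross-population score of an RBP's binding footprint combines two
parts. A Shannon-entropy weight ``S_f = 1 + f*log2(f) + (1-f)*log2(1-f)``
down-weights footprints covering about half of the panel (f near 0.5
carries one full bit of uncertainty, hence weight 0) and up-weights rare
annotations (f near 0 or 1, weight near 1). A selection-pressure term
``rho_adj = rho / rho_b`` compares the footprint's rare-variant fraction
``rho`` with the GC-matched genomic background ``rho_b``; values above 1
indicate purifying selection. The component score is their product, and a
variant takes the maximum over the RBPs binding it.

Binding hubs — positions bound by many distinct RBPs — are scored per
hub count H: strata below the hot threshold (top 5% of regulome bases)
contribute 0, the hot range is kernel-smoothed, and the ultra-hot range
(top 1%) is held constant at the hot maximum.

Cross-species constraint values are squashed to (0, 1) with a logistic
centred at the conventional constraint cutoff of 2; conserved-structure
membership is a 0/1 indicator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .context import GCBackground, PartitionedRegulome, VariantPanel
from .intervals import HubRuns, IntervalSet
from . import io as rio

PARTITIONS = ("coding", "noncoding")


# ---------------------------------------------------------------------------
# entropy weight

def entropy_weight(f: float) -> float:
    """``1 + f*log2(f) + (1-f)*log2(1-f)`` with the 0*log2(0)=0 convention."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {f}")
    h = 0.0
    if 0.0 < f < 1.0:
        h = f * math.log2(f) + (1.0 - f) * math.log2(1.0 - f)
    return 1.0 + h


def coverage_entropy(n_in: int, n_total: int) -> float:
    """Entropy weight of a coverage fraction ``f = n_in / n_total``."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_in <= n_total):
        raise ValueError("require 0 <= n_in <= n_total")
    return entropy_weight(n_in / n_total)


# ---------------------------------------------------------------------------
# rare-variant enrichment

@dataclass
class RareFractionStats:
    """Rare/common panel-variant counts in a region set, plus its GC."""

    n_r: int
    n_c: int
    g: float  # GC percentage of the region set
    defined: bool = True

    @property
    def rho(self) -> float:
        if not self.defined:
            return float("nan")
        return self.n_r / (self.n_r + self.n_c)


def region_gc_percent(regions: IntervalSet, genome) -> float:
    """GC percentage of a region set's sequence."""
    gc = at = 0
    for chrom, start, end in regions.intervals():
        seq = str(genome[chrom][start:end]).upper()
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        return float("nan")
    return 100.0 * gc / (gc + at)


def rare_fraction(
    panel: VariantPanel, regions: IntervalSet, genome=None,
) -> RareFractionStats:
    """Count rare/common panel variants inside ``regions``.

    Zero panel variants in the regions yields stats flagged undefined;
    downstream treats the corresponding score as 0.
    """
    if not regions:
        raise ValueError("regions must be nonempty")
    mask = panel.in_regions(regions)
    rare = panel.is_rare
    n_r = int((mask & rare).sum())
    n_c = int((mask & ~rare).sum())
    g = region_gc_percent(regions, genome) if genome is not None else float("nan")
    if n_r + n_c == 0:
        return RareFractionStats(0, 0, g, defined=False)
    return RareFractionStats(n_r, n_c, g)


def gc_adjusted_enrichment(
    stats: RareFractionStats, background: GCBackground
) -> float:
    """``rho_adj = rho / rho_b`` with the closest-GC background group."""
    if not stats.defined:
        raise ValueError("undefined rare-fraction stats")
    rho_b = background.lookup(stats.g)
    if rho_b == 0.0:
        raise ValueError("background group has zero rare-variant fraction")
    return stats.rho / rho_b


# ---------------------------------------------------------------------------
# per-RBP conservation table

@dataclass
class ConservationTable:
    """Per (RBP, partition) population-conservation scores.

    ``table`` columns: rbp_id, partition, n_in, f, s_f, n_r, n_c, rho, g,
    rho_b, rho_adj, score, defined. Queries return the maximum score over
    the RBPs whose matching-partition footprint contains the position.
    """

    table: pd.DataFrame
    partitioned: PartitionedRegulome

    _idx: Optional[pd.Series] = field(default=None, repr=False, compare=False)

    def score_at(self, chrom: str, pos: int) -> Tuple[float, Optional[str]]:
        """(max score, id of the achieving RBP) at a position; (0, None)
        when no peak covers it."""
        best, who = 0.0, None
        if self._idx is None:
            self._idx = self.table.set_index(["rbp_id", "partition"])["score"]
        idx = self._idx
        for rbp in self.partitioned.rbp_ids:
            if self.partitioned.coding[rbp].contains(chrom, pos):
                part = "coding"
            elif self.partitioned.noncoding[rbp].contains(chrom, pos):
                part = "noncoding"
            else:
                continue
            s = float(idx.get((rbp, part), 0.0))
            if s > best:
                best, who = s, rbp
        return best, who


def build_conservation_table(
    partitioned: PartitionedRegulome,
    panel: VariantPanel,
    background: GCBackground,
    genome,
) -> ConservationTable:
    """Score every (RBP, partition) footprint: ``rho_adj * S_f``.

    ``f`` is the fraction of the whole panel falling in the partitioned
    footprint (the panel size is the fixed denominator). Footprints with
    no panel variants score 0 and are flagged undefined.
    """
    n_total = len(panel)
    if n_total < 1:
        raise ValueError("empty variant panel")
    rows = []
    for rbp in partitioned.rbp_ids:
        for part in PARTITIONS:
            regions = (partitioned.coding if part == "coding"
                       else partitioned.noncoding)[rbp]
            if not regions:
                continue
            stats = rare_fraction(panel, regions, genome)
            n_in = stats.n_r + stats.n_c
            f = n_in / n_total
            s_f = entropy_weight(f)
            if stats.defined:
                try:
                    rho_adj = gc_adjusted_enrichment(stats, background)
                except ValueError:
                    warnings.warn(
                        f"{rbp}/{part}: no usable GC background; score 0"
                    )
                    rho_adj, score, defined = np.nan, 0.0, False
                else:
                    score, defined = rho_adj * s_f, True
            else:
                warnings.warn(
                    f"{rbp}/{part}: no panel variants in footprint; score 0"
                )
                rho_adj, score, defined = np.nan, 0.0, False
            rho_b = (stats.rho / rho_adj) if defined and rho_adj else np.nan
            rows.append((rbp, part, n_in, f, s_f, stats.n_r, stats.n_c,
                         stats.rho, stats.g, rho_b, rho_adj, score, defined))
    table = pd.DataFrame(rows, columns=[
        "rbp_id", "partition", "n_in", "f", "s_f", "n_r", "n_c", "rho",
        "g", "rho_b", "rho_adj", "score", "defined",
    ])
    return ConservationTable(table, partitioned)


# ---------------------------------------------------------------------------
# hub score table

def _nw_smooth(h_query: float, hs: np.ndarray, values: np.ndarray,
               bandwidth: float) -> float:
    """Nadaraya-Watson Gaussian-kernel regression on the integer H axis."""
    w = np.exp(-0.5 * ((hs - h_query) / bandwidth) ** 2)
    return float(np.sum(w * values) / np.sum(w))


@dataclass
class HubPartitionTable:
    """Hub-count scores for one partition (coding or noncoding)."""

    table: pd.DataFrame  # H, n_bases, rho_adj, s_h, raw, component
    h_hot: int
    h_ultra: int
    plateau: float
    bandwidth: float

    def component_at_h(self, h: int) -> float:
        if h < self.h_hot:
            return 0.0
        if h >= self.h_ultra:
            return self.plateau
        row = self.table[self.table["H"] == h]
        if len(row):
            return float(row["component"].iloc[0])
        hot = self.table[
            (self.table["H"] >= self.h_hot) & (self.table["H"] < self.h_ultra)
        ]
        if hot.empty:
            return self.plateau
        return _nw_smooth(
            h, hot["H"].to_numpy(float), hot["raw"].to_numpy(float),
            self.bandwidth,
        )


@dataclass
class HubScoreTable:
    """Hub scores for both partitions plus the track needed for queries."""

    partitions: Dict[str, HubPartitionTable]
    hub: HubRuns
    cds: IntervalSet

    def score_at(self, chrom: str, pos: int) -> Tuple[float, int]:
        h = self.hub.count_at(chrom, pos)
        if h == 0:
            return 0.0, 0
        part = "coding" if self.cds.contains(chrom, pos) else "noncoding"
        tab = self.partitions.get(part)
        if tab is None:
            return 0.0, h
        return tab.component_at_h(h), h


def _quantile_threshold(
    hs: np.ndarray, n_bases: np.ndarray, q: float
) -> int:
    """Smallest H whose upper-tail base fraction is <= q (base-weighted)."""
    order = np.argsort(hs)
    hs, n_bases = hs[order], n_bases[order]
    total = n_bases.sum()
    tail = np.cumsum(n_bases[::-1])[::-1] / total  # P(H' >= H)
    ok = np.flatnonzero(tail <= q)
    if len(ok) == 0:
        warnings.warn(
            f"no hub stratum reaches the top-{q:g} tail; using the maximum H"
        )
        return int(hs[-1])
    return int(hs[ok[0]])


def build_hub_score_table(
    hub: HubRuns,
    partitioned: PartitionedRegulome,
    panel: VariantPanel,
    background: GCBackground,
    genome,
    hot_q: float = 0.05,
    ultra_q: float = 0.01,
    bandwidth: float = 1.0,
) -> HubScoreTable:
    """Score each hub-count stratum per partition.

    Per H the stratum's bases are scored ``rho_adj|H * S_H``; strata below
    ``H_hot`` (top ``hot_q`` of partition bases) are zeroed, the hot range
    is smoothed with a Gaussian kernel on the integer H axis, and strata
    at or above ``H_ultra`` take a constant plateau equal to the maximum
    smoothed hot value.
    """
    n_total = len(panel)
    parts: Dict[str, HubPartitionTable] = {}
    for part in PARTITIONS:
        if part == "coding":
            restricted = hub.restricted(partitioned.cds)
        else:
            restricted = hub.restricted(
                _complement_within(hub, partitioned.cds)
            )
        hs = restricted.distinct_counts()
        if len(hs) == 0:
            continue
        n_bases = np.array(
            [restricted.stratum([h]).total_length for h in hs], dtype=float
        )
        h_hot = _quantile_threshold(hs, n_bases, hot_q)
        h_ultra = _quantile_threshold(hs, n_bases, ultra_q)
        if h_hot == h_ultra:
            warnings.warn(
                f"{part}: hot and ultra-hot thresholds coincide at H={h_hot}; "
                "plateau-only table"
            )
        rows = []
        for h, nb in zip(hs, n_bases):
            stratum = restricted.stratum([h])
            stats = rare_fraction(panel, stratum, genome)
            n_in = stats.n_r + stats.n_c
            s_h = entropy_weight(n_in / n_total)
            if stats.defined:
                try:
                    rho_adj = gc_adjusted_enrichment(stats, background)
                except ValueError:
                    rho_adj = np.nan
            else:
                rho_adj = np.nan
            raw = (rho_adj * s_h) if np.isfinite(rho_adj) else 0.0
            rows.append((int(h), int(nb), rho_adj, s_h, raw))
        df = pd.DataFrame(
            rows, columns=["H", "n_bases", "rho_adj", "s_h", "raw"]
        )
        hot = df[(df["H"] >= h_hot) & (df["H"] < h_ultra)]
        comp = np.zeros(len(df))
        if len(hot):
            hot_h = hot["H"].to_numpy(float)
            hot_raw = hot["raw"].to_numpy(float)
            smoothed = {
                int(h): _nw_smooth(h, hot_h, hot_raw, bandwidth)
                for h in hot_h
            }
            plateau = max(smoothed.values())
            for i, h in enumerate(df["H"]):
                if h < h_hot:
                    comp[i] = 0.0
                elif h >= h_ultra:
                    comp[i] = plateau
                else:
                    comp[i] = smoothed[int(h)]
        else:
            upper = df[df["H"] >= h_hot]
            plateau = float(upper["raw"].max()) if len(upper) else 0.0
            for i, h in enumerate(df["H"]):
                comp[i] = plateau if h >= h_ultra else 0.0
        df["component"] = comp
        parts[part] = HubPartitionTable(
            table=df, h_hot=h_hot, h_ultra=h_ultra,
            plateau=float(plateau), bandwidth=bandwidth,
        )
    if not parts:
        raise ValueError("hub track empty in both partitions")
    return HubScoreTable(parts, hub, partitioned.cds)


def _complement_within(hub: HubRuns, cds: IntervalSet) -> IntervalSet:
    """Regulome bases not in the CDS footprint (the noncoding partition)."""
    covered = hub.stratum(hub.distinct_counts().tolist())
    return covered.subtract(cds)


# ---------------------------------------------------------------------------
# cross-species conservation and structure

@dataclass
class GerpTransform:
    """Logistic squashing of per-base constraint values to (0, 1).

    ``midpoint`` is the value mapping to 0.5 (default 2, the conventional
    constraint cutoff); ``steepness`` defaults to ln(19) so midpoint±1
    map to 0.05 and 0.95, keeping the curve sharp at the cutoff.
    """

    midpoint: float = 2.0
    steepness: float = math.log(19.0)

    def __call__(self, value: float) -> float:
        return 1.0 / (1.0 + math.exp(-self.steepness * (value - self.midpoint)))


def gerp_component(
    value: Optional[float], transform: GerpTransform
) -> Tuple[float, bool]:
    """(score, missing-flag): missing or non-finite values score 0."""
    if value is None or not np.isfinite(value):
        return 0.0, True
    return transform(float(value)), False


class ValueTrack:
    """Step-function per-base values (bedGraph semantics)."""

    def __init__(self, steps: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.steps = steps

    @classmethod
    def from_bedgraph(cls, path) -> "ValueTrack":
        return cls(rio.read_bedgraph(path))

    def value_at(self, chrom: str, pos: int) -> Optional[float]:
        rec = self.steps.get(chrom)
        if rec is None:
            return None
        starts, ends, values = rec
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return None


def structure_component(
    chrom: str, pos: int, structural_regions: IntervalSet
) -> int:
    """1 iff the position lies in a conserved-structure interval."""
    return int(structural_regions.contains(chrom, pos))
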