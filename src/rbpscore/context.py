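"""Regulome construction: peak ingestion, coding/noncoding partition,
binding-hub track and the GC-stratified rare-variant background.

The regulome is the union of all RBP binding footprints. Within one RBP,
replicate peak files (and, by default, peaks from different cell lines)
are unioned and merged per strand, so the footprint counts each base
once. Rare-variant enrichment downstream is confounded by GC-dependent
coverage, so the genome is tiled into fixed-size bins, grouped by integer
GC percentage, and each group's background rare-variant fraction
``rho_b`` is estimated from the panel variants falling in its bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import HubRuns, IntervalSet, coverage_runs
from . import io as rio

logger = logging.getLogger("rbpscore")


# ---------------------------------------------------------------------------
# variant panel

@dataclass
class VariantPanel:
    """Population SNVs with derived allele frequencies.

    ``table`` has columns chrom, pos0 (0-based), ref, alt, daf.
    """

    table: pd.DataFrame
    daf_threshold: float = 0.005

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            if ((t["daf"] < 0) | (t["daf"] > 1)).any():
                raise ValueError("daf must lie in [0, 1]")
            if (t["ref"] == t["alt"]).any():
                raise ValueError("ref must differ from alt")

    @classmethod
    def from_vcf(
        cls, path: str | Path, af_info_key: str = "AF",
        daf_threshold: float = 0.005,
    ) -> "VariantPanel":
        return cls(rio.read_panel_vcf(path, af_info_key), daf_threshold)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def is_rare(self) -> np.ndarray:
        return (self.table["daf"].to_numpy() <= self.daf_threshold)

    def in_regions(self, regions: IntervalSet) -> np.ndarray:
        """Boolean mask of panel variants whose position lies in ``regions``."""
        mask = np.zeros(len(self.table), dtype=bool)
        for chrom, grp in self.table.groupby("chrom", sort=False):
            mask[grp.index.to_numpy()] = regions.contains_points(
                str(chrom), grp["pos0"].to_numpy()
            )
        return mask


# ---------------------------------------------------------------------------
# peaks

@dataclass
class RBPPeakCollection:
    """Merged, filtered binding peaks of a single RBP.

    ``peaks`` columns: chrom, start, end, strand, score (max over merged
    constituents). ``footprint`` is the strand-ignored merged interval set.
    """

    rbp_id: str
    cell_lines: Tuple[str, ...]
    peaks: pd.DataFrame
    provenance: Tuple[str, ...] = ()

    @property
    def footprint(self) -> IntervalSet:
        if self.peaks.empty:
            return IntervalSet.empty()
        return IntervalSet.from_intervals(
            self.peaks[["chrom", "start", "end"]].itertuples(index=False)
        )

    def peaks_at(self, chrom: str, pos: int) -> pd.DataFrame:
        p = self.peaks
        sel = (p["chrom"] == chrom) & (p["start"] <= pos) & (pos < p["end"])
        return p[sel]


def _merge_stranded(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping peaks per (chrom, strand); score = max merged."""
    rows = []
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        cur_score = -np.inf
        for start, end, score in zip(grp["start"], grp["end"], grp["score"]):
            if cur_s is None:
                cur_s, cur_e, cur_score = start, end, score
            elif start <= cur_e:
                cur_e = max(cur_e, end)
                cur_score = max(cur_score, score)
            else:
                rows.append((chrom, cur_s, cur_e, strand, cur_score))
                cur_s, cur_e, cur_score = start, end, score
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, strand, cur_score))
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "score"]
    )
    return out.sort_values(
        ["chrom", "start", "end", "strand"], ignore_index=True
    )


def parse_peak_file_name(path: str | Path) -> Tuple[str, str]:
    """Derive (rbp_id, cell_line) from a file named RBP_CELLLINE[_rep].*"""
    stem = Path(path).name.split(".")[0]
    parts = stem.split("_")
    rbp = parts[0]
    cell = parts[1] if len(parts) > 1 else "NA"
    return rbp, cell


def load_peaks(
    peak_files: Sequence,
    min_score: float = 1000.0,
    blacklist: IntervalSet | None = None,
    score_exact: bool = True,
    merge_cell_lines: bool = True,
) -> Dict[str, RBPPeakCollection]:
    """Ingest narrowPeak files into one merged collection per RBP.

    ``peak_files`` items are either paths (RBP and cell line parsed from
    the file name, ``RBP_CELLLINE[_rep]``) or ``(rbp_id, cell_line, path)``
    tuples. Peaks failing the score filter or overlapping the blacklist
    are dropped; replicate files for one RBP are unioned then merged per
    strand. With ``score_exact`` the ENCODE convention ``score == min``
    is applied, otherwise ``score >= min``.
    """
    blacklist = blacklist or IntervalSet.empty()
    per_rbp: Dict[str, List[pd.DataFrame]] = {}
    cells: Dict[str, set] = {}
    prov: Dict[str, List[str]] = {}
    for item in peak_files:
        if isinstance(item, (str, Path)):
            rbp, cell, path = (*parse_peak_file_name(item), item)
        else:
            rbp, cell, path = item
        df = rio.read_narrowpeak(path)
        if score_exact:
            df = df[df["score"] == min_score]
        else:
            df = df[df["score"] >= min_score]
        if not df.empty and blacklist:
            keep = []
            for chrom, grp in df.groupby("chrom", sort=False):
                bl = blacklist.data.get(str(chrom))
                if bl is None or not len(bl):
                    keep.extend(grp.index)
                    continue
                s = grp["start"].to_numpy()
                e = grp["end"].to_numpy()
                # a peak overlaps the blacklist iff some blacklist interval
                # starts before the peak ends and ends after the peak starts
                i = np.searchsorted(bl[:, 0], e, side="left") - 1
                ovl = (i >= 0) & (bl[np.maximum(i, 0), 1] > s)
                keep.extend(grp.index[~ovl])
            df = df.loc[sorted(keep)]
        key = rbp if merge_cell_lines else f"{rbp}:{cell}"
        per_rbp.setdefault(key, []).append(df)
        cells.setdefault(key, set()).add(cell)
        prov.setdefault(key, []).append(str(path))
    out: Dict[str, RBPPeakCollection] = {}
    for key in sorted(per_rbp):
        df = pd.concat(per_rbp[key], ignore_index=True)
        if df.empty:
            warnings.warn(f"RBP {key}: no peaks retained after filtering")
            merged = df[["chrom", "start", "end", "strand", "score"]]
        else:
            merged = _merge_stranded(df)
        out[key] = RBPPeakCollection(
            rbp_id=key,
            cell_lines=tuple(sorted(cells[key])),
            peaks=merged,
            provenance=tuple(prov[key]),
        )
    return out


# ---------------------------------------------------------------------------
# coding / noncoding partition

@dataclass
class PartitionedRegulome:
    """Per-RBP coding/noncoding split of peak footprints plus the union."""

    coding: Dict[str, IntervalSet]
    noncoding: Dict[str, IntervalSet]
    union: IntervalSet
    cds: IntervalSet

    @property
    def rbp_ids(self) -> List[str]:
        return sorted(self.coding)

    def union_partition(self, which: str) -> IntervalSet:
        parts = self.coding if which == "coding" else self.noncoding
        out = IntervalSet.empty()
        for fs in parts.values():
            out = out.union(fs)
        return out


def partition_by_coding(
    collections: Dict[str, RBPPeakCollection],
    cds: IntervalSet,
) -> PartitionedRegulome:
    """Split every RBP's footprint at the projected CDS footprint.

    A base is coding iff it overlaps any CDS exon of any transcript; per
    RBP, |coding| + |noncoding| equals the footprint length exactly.
    """
    coding, noncoding = {}, {}
    union = IntervalSet.empty()
    for rbp, coll in collections.items():
        fp = coll.footprint
        coding[rbp] = fp.intersect(cds)
        noncoding[rbp] = fp.subtract(cds)
        union = union.union(fp)
    return PartitionedRegulome(coding, noncoding, union, cds)


# ---------------------------------------------------------------------------
# hub track

def build_hub_track(
    collections: Dict[str, RBPPeakCollection] | Sequence[RBPPeakCollection],
) -> HubRuns:
    """Per-base count H of distinct RBPs bound, as run-length runs.

    Each RBP's merged footprint contributes at most one per base, so
    replicates and strands never double-count an RBP.
    """
    if isinstance(collections, dict):
        colls = [collections[k] for k in sorted(collections)]
    else:
        colls = list(collections)
    if not colls:
        raise ValueError("need at least one peak collection")
    return coverage_runs([c.footprint for c in colls])


# ---------------------------------------------------------------------------
# GC background

@dataclass
class GCBackground:
    """Background rare-variant fraction stratified by bin GC percentage.

    ``groups`` maps integer GC percent to (n_bins, n_rare, n_common).
    Lookup returns the usable group (>=1 panel variant) with the closest
    GC, ties broken toward lower GC.
    """

    bin_size: int
    groups: Dict[int, Tuple[int, int, int]]

    def usable_groups(self) -> Dict[int, float]:
        out = {}
        for g, (_, nr, nc) in sorted(self.groups.items()):
            if nr + nc > 0:
                out[g] = nr / (nr + nc)
        return out

    def lookup(self, g: float) -> float:
        """Background rho_b for an arbitrary GC percentage ``g``."""
        usable = self.usable_groups()
        if not usable:
            raise ValueError("no usable GC background group")
        best = min(usable, key=lambda lbl: (abs(lbl - g), lbl))
        return usable[best]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, nb, nr, nc, nr / (nr + nc) if nr + nc else np.nan)
            for g, (nb, nr, nc) in sorted(self.groups.items())
        ]
        return pd.DataFrame(
            rows, columns=["gc_percent", "n_bins", "n_rare", "n_common", "rho_b"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bin_size: int) -> "GCBackground":
        groups = {
            int(r.gc_percent): (int(r.n_bins), int(r.n_rare), int(r.n_common))
            for r in df.itertuples()
        }
        return cls(bin_size=bin_size, groups=groups)


def _merge_small_groups(
    groups: Dict[int, List[int]], min_bins: int
) -> Dict[int, List[int]]:
    """Iteratively absorb groups below the bin minimum into their nearest
    GC neighbour (ties toward lower GC)."""
    groups = {g: list(v) for g, v in groups.items()}
    while len(groups) > 1:
        small = [(v[0], g) for g, v in groups.items() if v[0] < min_bins]
        if not small:
            break
        _, g = min(small)  # fewest bins, ties toward lower GC
        rest = [h for h in groups if h != g]
        target = min(rest, key=lambda h: (abs(h - g), h))
        for i in range(3):
            groups[target][i] += groups[g][i]
        del groups[g]
    return groups


def bin_gc_percent(seq: str) -> float:
    """Integer-rounded GC percentage of a bin sequence (nan if all N)."""
    frac = rio.gc_fraction(seq)
    if np.isnan(frac):
        return float("nan")
    return float(round(frac * 100))


def build_gc_background(
    genome,
    panel: VariantPanel,
    bin_size: int = 500,
    min_bins_per_group: int = 50,
) -> GCBackground:
    """Tile the genome into ``bin_size`` bins, group by integer GC percent,
    and estimate each group's background rare-variant fraction from the
    panel variants that fall in its bins.

    ``genome`` is a mapping from chromosome name to sequence (e.g. a
    ``pyfaidx.Fasta``). Groups with fewer than ``min_bins_per_group``
    bins are merged into the nearest GC group; groups left without any
    panel variant are excluded from lookup with a warning.
    """
    # integer GC group per bin, per chromosome
    bin_groups: Dict[str, np.ndarray] = {}
    agg: Dict[int, List[int]] = {}
    for chrom in sorted(genome.keys() if hasattr(genome, "keys") else genome):
        seq = str(genome[chrom][:]) if hasattr(genome[chrom], "__getitem__") \
            else str(genome[chrom])
        n_bins = (len(seq) + bin_size - 1) // bin_size
        gcs = np.full(n_bins, -1, dtype=np.int64)
        for b in range(n_bins):
            g = bin_gc_percent(seq[b * bin_size:(b + 1) * bin_size])
            if not np.isnan(g):
                gcs[b] = int(g)
                rec = agg.setdefault(int(g), [0, 0, 0])
                rec[0] += 1
        bin_groups[chrom] = gcs
    if not agg:
        raise ValueError("no scorable genome bins")

    # panel variants -> containing bin -> group (vectorized tally)
    rare = panel.is_rare
    for chrom, grp in panel.table.groupby("chrom", sort=False):
        gcs = bin_groups.get(str(chrom))
        if gcs is None:
            continue
        bins = grp["pos0"].to_numpy() // bin_size
        ok = (bins >= 0) & (bins < len(gcs))
        g = gcs[bins[ok]]
        r = rare[grp.index.to_numpy()[ok]]
        valid = g >= 0
        key = g[valid] * 2 + r[valid].astype(np.int64)
        if len(key):
            counts = np.bincount(key)
            for k in np.flatnonzero(counts):
                agg[int(k // 2)][1 if k % 2 else 2] += int(counts[k])

    merged = _merge_small_groups(agg, min_bins_per_group)
    empty = [g for g, v in merged.items() if v[1] + v[2] == 0]
    if empty:
        warnings.warn(
            f"GC groups without panel variants excluded from lookup: {empty}"
        )
    return GCBackground(
        bin_size=bin_size,
        groups={g: tuple(v) for g, v in sorted(merged.items())},
    )
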