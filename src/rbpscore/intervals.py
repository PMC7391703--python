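"""Half-open genomic interval sets and sweep-line primitives.

All coordinates are 0-based, half-open ``[start, end)``. An
:class:`IntervalSet` stores, per chromosome, a sorted, merged ``(N, 2)``
integer array, so set algebra (union / intersection / subtraction),
point-membership queries and per-base coverage counting are simple
``numpy`` sweeps. These primitives underpin the regulome partition and
the binding-hub track, so they are implemented and tested here rather
than delegated to an external interval engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np

Interval = Tuple[str, int, int]


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def merge_starts_ends(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Merge possibly-overlapping intervals into a sorted disjoint (N,2) array.

    Touching intervals ([0,5) and [5,8)) are coalesced.
    """
    if len(starts) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    starts = np.asarray(starts, dtype=np.int64)[order]
    ends = np.asarray(ends, dtype=np.int64)[order]
    # running maximum of ends; a new block starts where start > max(previous ends)
    run_max = np.maximum.accumulate(ends)
    new_block = np.empty(len(starts), dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > run_max[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    out = np.empty((n_blocks, 2), dtype=np.int64)
    out[:, 0] = starts[new_block]
    out[:, 1] = np.maximum.reduceat(run_max, np.flatnonzero(new_block))
    return out


class IntervalSet:
    """A merged, sorted set of half-open intervals keyed by chromosome."""

    def __init__(self, data: Dict[str, np.ndarray] | None = None):
        # data values must already be sorted & disjoint
        self.data: Dict[str, np.ndarray] = data or {}

    @classmethod
    def from_intervals(cls, intervals: Iterable[Sequence]) -> "IntervalSet":
        """Build from (chrom, start, end[, ...]) records; merges overlaps."""
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for rec in intervals:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            if start >= end:
                raise ValueError(f"empty interval [{start}, {end}) on {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end))
        data = {}
        for chrom, ivs in by_chrom.items():
            arr = np.asarray(ivs, dtype=np.int64)
            data[chrom] = merge_starts_ends(arr[:, 0], arr[:, 1])
        return cls(data)

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls({})

    def __bool__(self) -> bool:
        return any(len(a) for a in self.data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        keys = {c for c, a in self.data.items() if len(a)}
        okeys = {c for c, a in other.data.items() if len(a)}
        if keys != okeys:
            return False
        return all(np.array_equal(self.data[c], other.data[c]) for c in keys)

    def intervals(self) -> Iterator[Interval]:
        for chrom in sorted(self.data):
            for start, end in self.data[chrom]:
                yield chrom, int(start), int(end)

    @property
    def total_length(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self.data.values())
        )

    def union(self, other: "IntervalSet") -> "IntervalSet":
        data = {}
        for chrom in set(self.data) | set(other.data):
            parts = [
                d[chrom] for d in (self.data, other.data) if chrom in d
            ]
            arr = np.concatenate(parts)
            data[chrom] = merge_starts_ends(arr[:, 0], arr[:, 1])
        return IntervalSet(data)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        data = {}
        for chrom in set(self.data) & set(other.data):
            a, b = self.data[chrom], other.data[chrom]
            if not len(a) or not len(b):
                continue
            # two-pointer sweep
            out = []
            i = j = 0
            while i < len(a) and j < len(b):
                lo = max(a[i, 0], b[j, 0])
                hi = min(a[i, 1], b[j, 1])
                if lo < hi:
                    out.append((lo, hi))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if out:
                data[chrom] = np.asarray(out, dtype=np.int64)
        return IntervalSet(data)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        data = {}
        for chrom, a in self.data.items():
            if not len(a):
                continue
            b = other.data.get(chrom)
            if b is None or not len(b):
                data[chrom] = a.copy()
                continue
            out = []
            j = 0
            for start, end in a:
                cur = start
                while j < len(b) and b[j, 1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k, 0] < end:
                    if b[k, 0] > cur:
                        out.append((cur, b[k, 0]))
                    cur = max(cur, b[k, 1])
                    k += 1
                if cur < end:
                    out.append((cur, end))
            if out:
                data[chrom] = np.asarray(out, dtype=np.int64)
        return IntervalSet(data)

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership test for 0-based positions."""
        positions = np.asarray(positions, dtype=np.int64)
        arr = self.data.get(chrom)
        if arr is None or not len(arr):
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(len(positions), dtype=bool)
        res[ok] = positions[ok] < arr[idx[ok], 1]
        return res

    def contains(self, chrom: str, pos: int) -> bool:
        return bool(self.contains_points(chrom, np.array([pos]))[0])


@dataclass
class HubRuns:
    """Run-length encoded per-base count of distinct covering sets.

    ``runs[chrom]`` is a tuple ``(starts, ends, counts)`` of equal-length
    arrays; runs are disjoint, sorted and have count >= 1. Positions not
    covered by any run have count 0.
    """

    runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def count_at(self, chrom: str, pos: int) -> int:
        r = self.runs.get(chrom)
        if r is None:
            return 0
        starts, ends, counts = r
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return int(counts[i])
        return 0

    def stratum(self, values: Sequence[int]) -> IntervalSet:
        """Interval set of all runs whose count is in ``values``."""
        wanted = set(int(v) for v in values)
        data = {}
        for chrom, (starts, ends, counts) in self.runs.items():
            mask = np.isin(counts, list(wanted))
            if mask.any():
                data[chrom] = np.stack(
                    [starts[mask], ends[mask]], axis=1
                ).astype(np.int64)
        # runs with equal counts may touch after filtering; merge them
        return IntervalSet(
            {c: merge_starts_ends(a[:, 0], a[:, 1]) for c, a in data.items()}
        )

    def distinct_counts(self) -> np.ndarray:
        if not self.runs:
            return np.array([], dtype=np.int64)
        return np.unique(
            np.concatenate([c for _, _, c in self.runs.values()])
        )

    def restricted(self, region: IntervalSet) -> "HubRuns":
        """Clip runs to ``region``, preserving counts."""
        out: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, counts) in self.runs.items():
            reg = region.data.get(chrom)
            if reg is None or not len(reg):
                continue
            new_s, new_e, new_c = [], [], []
            j = 0
            for s, e, c in zip(starts, ends, counts):
                while j < len(reg) and reg[j, 1] <= s:
                    j += 1
                k = j
                while k < len(reg) and reg[k, 0] < e:
                    lo, hi = max(s, reg[k, 0]), min(e, reg[k, 1])
                    if lo < hi:
                        new_s.append(lo)
                        new_e.append(hi)
                        new_c.append(c)
                    k += 1
            if new_s:
                out[chrom] = (
                    np.asarray(new_s, dtype=np.int64),
                    np.asarray(new_e, dtype=np.int64),
                    np.asarray(new_c, dtype=np.int64),
                )
        return HubRuns(out)


def coverage_runs(footprints: Sequence[IntervalSet]) -> HubRuns:
    """Sweep-line per-base count of how many of ``footprints`` cover each base.

    Each element contributes at most 1 per base (its intervals are already
    merged), so the count is the number of distinct sets covering a position.
    """
    chroms = sorted({c for fs in footprints for c in fs.data})
    runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in chroms:
        events: List[np.ndarray] = []
        for fs in footprints:
            arr = fs.data.get(chrom)
            if arr is None or not len(arr):
                continue
            ev = np.empty((2 * len(arr), 2), dtype=np.int64)
            ev[0::2, 0] = arr[:, 0]
            ev[0::2, 1] = 1
            ev[1::2, 0] = arr[:, 1]
            ev[1::2, 1] = -1
            events.append(ev)
        if not events:
            continue
        allev = np.concatenate(events)
        pos = np.unique(allev[:, 0])
        delta = np.zeros(len(pos), dtype=np.int64)
        idx = np.searchsorted(pos, allev[:, 0])
        np.add.at(delta, idx, allev[:, 1])
        counts = np.cumsum(delta)[:-1]
        starts, ends = pos[:-1], pos[1:]
        keep = counts > 0
        runs[chrom] = (starts[keep], ends[keep], counts[keep])
    return HubRuns(runs)
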