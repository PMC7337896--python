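"""Genomic interval algebra.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
This module supplies the primitives every downstream stage is built on —
sorting, gap-tolerant merging (the cluster-building primitive), nearest-neighbor
distances, overlap queries, seeded subsampling and TSS windows.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "NeighborDistances",
    "sort_intervals",
    "merge_with_gap",
    "nearest_neighbor_distances",
    "overlaps_any",
    "subsample",
    "window_around",
]

_VALID_STRANDS = {None, "+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    ``name``/``score``/``strand``/``extra`` carry optional BED columns so that
    narrowPeak-style files round-trip; they never influence the algebra.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval requires a chromosome name")
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Edge-to-edge gap in bp; 0 when overlapping or book-ended, None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Members may overlap (raw peak sets do). ``is_sorted`` records whether the
    collection is ordered by ``(chrom, start, end)``.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), *, is_sorted: bool = False):
        self._intervals: list[GenomicInterval] = list(intervals)
        self.is_sorted = bool(is_sorted)
        self._index: dict[str, tuple[list[int], list[int], list[GenomicInterval]]] | None = None

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, sorted={self.is_sorted})"

    @property
    def intervals(self) -> list[GenomicInterval]:
        return list(self._intervals)

    def sort(self) -> "IntervalSet":
        """Return a copy sorted by (chrom, start, end)."""
        if self.is_sorted:
            return IntervalSet(self._intervals, is_sorted=True)
        return IntervalSet(sorted(self._intervals, key=GenomicInterval.key), is_sorted=True)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = defaultdict(list)
        for iv in self._intervals:
            out[iv.chrom].append(iv)
        return dict(out)

    # -- overlap index -------------------------------------------------
    def _overlap_index(self):
        """Per-chromosome (sorted starts, running max of ends, intervals)."""
        if self._index is None:
            index = {}
            for chrom, ivs in self.by_chrom().items():
                ivs = sorted(ivs, key=GenomicInterval.key)
                starts = [iv.start for iv in ivs]
                max_ends: list[int] = []
                cur = 0
                for iv in ivs:
                    cur = max(cur, iv.end)
                    max_ends.append(cur)
                index[chrom] = (starts, max_ends, ivs)
            self._index = index
        return self._index


def sort_intervals(s: IntervalSet) -> IntervalSet:
    """Sort a set by (chrom, start, end); validation happens at interval construction."""
    return s.sort()


def merge_with_gap(s: IntervalSet, gap: int = 10_000) -> IntervalSet:
    """Merge intervals whose edge-to-edge distance is at most ``gap`` bp.

    Overlapping and book-ended intervals always merge; each output interval is
    the union span of its members and outputs are pairwise separated by gaps
    strictly greater than ``gap``. Equivalent to ``bedtools merge -d gap``.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    srt = s.sort()
    merged: list[GenomicInterval] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for iv in srt:
        if iv.chrom != cur_chrom or iv.start - cur_end > gap:
            if cur_chrom is not None:
                merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
        else:
            cur_end = max(cur_end, iv.end)
    if cur_chrom is not None:
        merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return IntervalSet(merged, is_sorted=True)


@dataclass
class NeighborDistances:
    """Nearest same-chromosome neighbor distances.

    ``per_interval`` is aligned with the input order and holds ``None`` for
    intervals that are alone on their chromosome; ``n_omitted`` counts those.
    """

    per_interval: list[int | None]
    n_omitted: int
    mode: str = "edge"

    @property
    def values(self) -> list[int]:
        return [d for d in self.per_interval if d is not None]


def nearest_neighbor_distances(s: IntervalSet, mode: str = "edge") -> NeighborDistances:
    """Distance from each interval to its closest same-chromosome neighbor.

    ``mode="edge"`` measures the gap between nearest edges (0 for overlapping
    or book-ended intervals); ``mode="midpoint"`` measures |midpoint
    difference|. Intervals alone on their chromosome are omitted.
    """
    if len(s) == 0:
        raise ValueError("nearest_neighbor_distances requires a non-empty set")
    if mode not in ("edge", "midpoint"):
        raise ValueError(f"unknown distance mode {mode!r}")

    per: list[int | None] = [None] * len(s)
    order = sorted(range(len(s)), key=lambda i: s[i].key())
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for i in order:
        by_chrom[s[i].chrom].append(i)

    n_omitted = 0
    for idxs in by_chrom.values():
        if len(idxs) < 2:
            n_omitted += len(idxs)
            continue
        if mode == "edge":
            # sorted by start; nearest earlier interval is the one with max end
            max_end_before: list[int | None] = [None] * len(idxs)
            cur: int | None = None
            for k, i in enumerate(idxs):
                max_end_before[k] = cur
                cur = s[i].end if cur is None else max(cur, s[i].end)
            for k, i in enumerate(idxs):
                cands: list[int] = []
                if max_end_before[k] is not None:
                    cands.append(s[i].start - max_end_before[k])
                if k + 1 < len(idxs):
                    cands.append(s[idxs[k + 1]].start - s[i].end)
                per[i] = max(0, min(cands))
        else:
            mids = sorted(idxs, key=lambda i: s[i].midpoint)
            for k, i in enumerate(mids):
                cands = []
                if k > 0:
                    cands.append(abs(s[i].midpoint - s[mids[k - 1]].midpoint))
                if k + 1 < len(mids):
                    cands.append(abs(s[mids[k + 1]].midpoint - s[i].midpoint))
                per[i] = int(min(cands))
    return NeighborDistances(per, n_omitted, mode)


def overlaps_any(query: GenomicInterval, s: IntervalSet) -> bool:
    """True iff ``query`` shares at least one bp with some member of ``s``.

    Half-open semantics: ``[a,b)`` and ``[b,c)`` do not overlap.
    """
    index = s._overlap_index()
    entry = index.get(query.chrom)
    if entry is None:
        return False
    starts, max_ends, ivs = entry
    # members with start < query.end are the only overlap candidates
    hi = bisect.bisect_left(starts, query.end)
    if hi == 0:
        return False
    # among those, any running max end beyond query.start means an overlap
    return max_ends[hi - 1] > query.start


def subsample(s: IntervalSet, n: int, seed: int) -> IntervalSet:
    """Uniform sample of ``n`` members without replacement, deterministic in ``seed``."""
    if n > len(s):
        raise ValueError(f"cannot subsample {n} from a set of {len(s)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(s), size=n, replace=False)
    return IntervalSet([s[i] for i in sorted(chosen)], is_sorted=s.is_sorted)


def window_around(
    chrom: str, position: int, radius: int, chrom_length: int | None = None
) -> GenomicInterval:
    """The window ``[max(0, position - radius), position + radius)``.

    Clips at 0 on the left; clips at ``chrom_length`` on the right when given.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    start = max(0, position - radius)
    end = position + radius
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(chrom, start, end)
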