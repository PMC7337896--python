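"""ERBS cluster construction and clustering statistics.

Sites within a gap threshold (default 10 kb, edge-to-edge) of each other are
merged into clusters — the connected components of the "gap <= d" relation per
chromosome. Summaries report the fraction of sites with a close neighbor and
the fraction of merged windows holding more than one site; the same summary is
computed on randomly subsampled control site sets (DNase-hypersensitive or
CTCF sites in the original study design) for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalSet,
    nearest_neighbor_distances,
    subsample,
)
from .motifs import ErbsRecord

__all__ = [
    "Cluster",
    "ClusteringSummary",
    "ControlSummary",
    "build_clusters",
    "clustering_summary",
    "control_comparison",
    "distance_histogram",
]


@dataclass
class Cluster:
    """A merged group of one or more ER binding sites."""

    cluster_id: str
    span: GenomicInterval
    members: list[ErbsRecord]

    @property
    def size(self) -> int:
        return len(self.members)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster requires at least one member")
        for m in self.members:
            if not self.span.overlaps(m.interval) or m.interval.start < self.span.start or m.interval.end > self.span.end:
                raise ValueError(f"cluster {self.cluster_id} span does not cover member")


def build_clusters(
    sites: Sequence[ErbsRecord] | Iterable[ErbsRecord], gap: int = 10_000
) -> list[Cluster]:
    """Partition sites into clusters: same-chromosome chains with gaps <= ``gap``."""
    if gap < 0:
        raise ValueError("gap must be non-negative")
    records = sorted(sites, key=lambda r: r.interval.key())
    clusters: list[Cluster] = []
    current: list[ErbsRecord] = []
    cur_end = 0

    def flush() -> None:
        if not current:
            return
        chrom = current[0].interval.chrom
        start = min(r.interval.start for r in current)
        end = max(r.interval.end for r in current)
        cid = f"cluster_{len(clusters):05d}"
        clusters.append(Cluster(cid, GenomicInterval(chrom, start, end, name=cid), list(current)))

    for rec in records:
        iv = rec.interval
        if current and iv.chrom == current[0].interval.chrom and iv.start - cur_end <= gap:
            current.append(rec)
            cur_end = max(cur_end, iv.end)
        else:
            flush()
            current = [rec]
            cur_end = iv.end
    flush()
    return clusters


@dataclass(frozen=True)
class ClusteringSummary:
    """Headline clustering statistics for one site set at one gap threshold."""

    n_sites: int
    n_clusters: int
    n_multi_clusters: int
    frac_sites_with_neighbor: float
    frac_multi_windows: float

    def __post_init__(self) -> None:
        assert 0 <= self.frac_sites_with_neighbor <= 1
        assert 0 <= self.frac_multi_windows <= 1
        assert self.n_clusters <= self.n_sites


def _as_interval_set(sites) -> IntervalSet:
    if isinstance(sites, IntervalSet):
        return sites
    ivs = [s.interval if isinstance(s, ErbsRecord) else s for s in sites]
    return IntervalSet(ivs)


def clustering_summary(
    sites, gap: int = 10_000, mode: str = "edge"
) -> ClusteringSummary:
    """Compute the five clustering statistics for a site set.

    ``frac_sites_with_neighbor`` uses nearest-neighbor distances (``mode``
    edge or midpoint) thresholded at ``gap``, with all sites in the
    denominator; ``frac_multi_windows`` is the fraction of merged clusters
    holding more than one site.
    """
    s = _as_interval_set(sites)
    if len(s) == 0:
        raise ValueError("clustering_summary requires at least one site")
    nnd = nearest_neighbor_distances(s, mode=mode)
    with_neighbor = sum(1 for d in nnd.per_interval if d is not None and d <= gap)
    records = [ErbsRecord(interval=iv) for iv in s]
    clusters = build_clusters(records, gap)
    n_multi = sum(1 for c in clusters if c.size >= 2)
    return ClusteringSummary(
        n_sites=len(s),
        n_clusters=len(clusters),
        n_multi_clusters=n_multi,
        frac_sites_with_neighbor=with_neighbor / len(s),
        frac_multi_windows=n_multi / len(clusters),
    )


@dataclass(frozen=True)
class ControlSummary:
    """One subsampled-control clustering summary, with seed provenance."""

    control: str
    seed: int
    summary: ClusteringSummary


def control_comparison(
    control_sets: Mapping[str, IntervalSet],
    n: int,
    seeds: Sequence[int],
    gap: int = 10_000,
    mode: str = "edge",
) -> list[ControlSummary]:
    """Subsample each control set to ``n`` sites per seed and summarize.

    Mirrors the study's control: draw the ERBS count from a larger control
    region set (without replacement) and run the identical cluster analysis.
    """
    out: list[ControlSummary] = []
    for name, cset in control_sets.items():
        if len(cset) < n:
            raise ValueError(
                f"control {name!r} has {len(cset)} members, cannot subsample {n}"
            )
        for seed in seeds:
            sub = subsample(cset, n, seed)
            out.append(ControlSummary(name, int(seed), clustering_summary(sub, gap, mode)))
    return out


def distance_histogram(
    sites, bin_width: int = 1_000, max_distance: int = 100_000, mode: str = "edge"
) -> pd.DataFrame:
    """Histogram of nearest-neighbor distances (final bin is open-ended).

    Bin counts sum to the number of sites with a same-chromosome neighbor.
    """
    s = _as_interval_set(sites)
    values = np.asarray(nearest_neighbor_distances(s, mode=mode).values, dtype=float)
    edges = np.arange(0, max_distance + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(values, bins=np.append(edges, np.inf))
    return pd.DataFrame({"bin_start": edges.astype(int), "count": counts})
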