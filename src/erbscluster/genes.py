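"""Cluster-to-gene association through TSS windows.

A cluster belongs to a gene's neighborhood when its span overlaps the +/-100 kb
window around the gene's single annotated TSS (window-overlap semantics, not
midpoint containment). Every gene — up-, down- and not-regulated — receives an
annotation so that class-wise proportions are computable for all three
classes, and the three activity states (active / inactive-only / no cluster)
partition the genes exactly.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import ClusterClassification
from .clustering import Cluster
from .intervals import window_around
from .io import GeneRecord

__all__ = [
    "GeneClusterAnnotation",
    "FoldChangeGroups",
    "assign_clusters_to_genes",
    "class_proportions",
    "foldchange_partition",
]

_PARTITION_KEYS = ("multi_cluster", "active_cluster")


@dataclass(frozen=True)
class GeneClusterAnnotation:
    """Per-gene summary of the ERBS clusters within the TSS window."""

    gene_id: str
    clusters_in_window: tuple[str, ...]
    has_multi_cluster: bool
    has_active_cluster: bool
    has_inactive_only: bool
    has_mmp17_like: bool
    has_cish_like: bool

    def __post_init__(self) -> None:
        assert not (self.has_inactive_only and (self.has_active_cluster or not self.clusters_in_window))
        assert not ((self.has_mmp17_like or self.has_cish_like) and not self.has_active_cluster)


def assign_clusters_to_genes(
    clusters: Sequence[Cluster],
    genes: Sequence[GeneRecord],
    radius: int = 100_000,
    classifications: Mapping[str, ClusterClassification] | None = None,
) -> list[GeneClusterAnnotation]:
    """Annotate every gene with the clusters whose span overlaps its TSS window.

    When ``classifications`` are supplied the activity flags are filled from
    them; otherwise all clusters count as unclassified (activity flags False,
    ``has_inactive_only`` true for any gene with clusters).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    by_chrom: dict[str, tuple[list[int], list[int], list[Cluster]]] = {}
    for chrom in {c.span.chrom for c in clusters}:
        cs = sorted((c for c in clusters if c.span.chrom == chrom), key=lambda c: c.span.key())
        starts = [c.span.start for c in cs]
        max_ends, cur = [], 0
        for c in cs:
            cur = max(cur, c.span.end)
            max_ends.append(cur)
        by_chrom[chrom] = (starts, max_ends, cs)

    annotations = []
    for g in genes:
        win = window_around(g.chrom, g.tss, radius)
        hits: list[Cluster] = []
        entry = by_chrom.get(g.chrom)
        if entry is not None:
            starts, max_ends, cs = entry
            hi = bisect.bisect_left(starts, win.end)
            # walk left only while some candidate may still reach the window
            for k in range(hi - 1, -1, -1):
                if max_ends[k] <= win.start:
                    break
                if cs[k].span.end > win.start:
                    hits.append(cs[k])
            hits.reverse()
        ids = tuple(c.cluster_id for c in hits)
        if classifications is not None:
            cl = [classifications[c.cluster_id] for c in hits]
            has_active = any(x.active for x in cl)
            has_mmp17 = any(x.mmp17_like for x in cl)
            has_cish = any(x.cish_like for x in cl)
        else:
            has_active = has_mmp17 = has_cish = False
        annotations.append(
            GeneClusterAnnotation(
                gene_id=g.gene_id,
                clusters_in_window=ids,
                has_multi_cluster=any(c.size >= 2 for c in hits),
                has_active_cluster=has_active,
                has_inactive_only=bool(ids) and not has_active,
                has_mmp17_like=has_mmp17,
                has_cish_like=has_cish,
            )
        )
    return annotations


def class_proportions(
    annotations: Sequence[GeneClusterAnnotation], genes: Sequence[GeneRecord]
) -> pd.DataFrame:
    """Per regulation class: gene counts and cluster-presence proportions.

    Rows are indexed by reg_class with columns ``n_genes``,
    ``frac_multi_cluster`` and the mutually exclusive activity partition
    ``frac_active`` / ``frac_inactive_only`` / ``frac_no_cluster``.
    """
    ann_by_gene = {a.gene_id: a for a in annotations}
    missing = [g.gene_id for g in genes if g.gene_id not in ann_by_gene]
    if missing:
        raise ValueError(f"genes without annotation: {missing[:5]}")
    rows = {}
    for reg in ("up", "down", "not"):
        members = [g for g in genes if g.reg_class == reg]
        if not members:
            rows[reg] = dict(
                n_genes=0, frac_multi_cluster=np.nan, frac_active=np.nan,
                frac_inactive_only=np.nan, frac_no_cluster=np.nan,
            )
            continue
        anns = [ann_by_gene[g.gene_id] for g in members]
        n = len(anns)
        rows[reg] = dict(
            n_genes=n,
            frac_multi_cluster=sum(a.has_multi_cluster for a in anns) / n,
            frac_active=sum(a.has_active_cluster for a in anns) / n,
            frac_inactive_only=sum(a.has_inactive_only for a in anns) / n,
            frac_no_cluster=sum(not a.clusters_in_window for a in anns) / n,
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "reg_class"
    return df


@dataclass
class FoldChangeGroups:
    """log2 fold changes of up-regulated genes split by a cluster feature."""

    key: str
    with_feature: np.ndarray
    without_feature: np.ndarray


def foldchange_partition(
    annotations: Sequence[GeneClusterAnnotation],
    genes: Sequence[GeneRecord],
    partition_key: str = "active_cluster",
) -> FoldChangeGroups:
    """Split up-regulated genes by cluster feature presence for the rank test.

    ``multi_cluster`` reproduces the dispersed-vs-clustered comparison;
    ``active_cluster`` the active-vs-no-active comparison.
    """
    if partition_key not in _PARTITION_KEYS:
        raise ValueError(f"partition_key must be one of {_PARTITION_KEYS}")
    ann_by_gene = {a.gene_id: a for a in annotations}
    with_f, without_f = [], []
    n_up = 0
    for g in genes:
        if g.reg_class != "up":
            continue
        n_up += 1
        a = ann_by_gene.get(g.gene_id)
        if a is None:
            raise ValueError(f"up-regulated gene {g.gene_id} has no annotation")
        flag = a.has_multi_cluster if partition_key == "multi_cluster" else a.has_active_cluster
        (with_f if flag else without_f).append(g.log2fc)
    if n_up == 0:
        warnings.warn("no up-regulated genes; fold-change groups are empty", stacklevel=2)
    return FoldChangeGroups(
        key=partition_key,
        with_feature=np.asarray(with_f, dtype=float),
        without_feature=np.asarray(without_f, dtype=float),
    )
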