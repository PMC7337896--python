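"""Cluster activity classification.

A cluster is *active* when it contains at least one site with a full ERE and
at least one site overlapping basal (vehicle-condition) H3K27ac. Active
clusters split into two architectures:

* hierarchical / MMP17-like — a single member carries both the full ERE and
  the basal acetylation;
* synergistic / CISH-like — the full ERE and the basal acetylation sit on
  distinct members.

One cluster can satisfy both definitions (e.g. three members). Singleton
clusters are classifiable: a lone dual-feature site is an active, MMP17-like
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .clustering import Cluster
from .intervals import IntervalSet, overlaps_any
from .motifs import ErbsRecord

__all__ = [
    "ClusterClassification",
    "ClassificationCensus",
    "mark_basal_k27ac",
    "classify_cluster",
    "classify_clusters",
    "classification_census",
]


@dataclass(frozen=True)
class ClusterClassification:
    cluster_id: str
    size: int
    n_full_ere_members: int
    n_basal_k27ac_members: int
    active: bool
    mmp17_like: bool
    cish_like: bool

    def __post_init__(self) -> None:
        assert self.active == (self.n_full_ere_members >= 1 and self.n_basal_k27ac_members >= 1)
        assert not (self.mmp17_like and not self.active)
        assert not (self.cish_like and not self.active)


def mark_basal_k27ac(
    sites: Sequence[ErbsRecord], k27_peaks: IntervalSet
) -> list[ErbsRecord]:
    """Set ``basal_k27ac`` on each site by 1-bp overlap with the basal peak set."""
    return [replace(r, basal_k27ac=overlaps_any(r.interval, k27_peaks)) for r in sites]


def classify_cluster(c: Cluster) -> ClusterClassification:
    """Classify one cluster from its members' existence flags.

    MMP17-like: some member has both the full ERE and basal H3K27ac.
    CISH-like: members i != j where i has the full ERE and j the acetylation.
    """
    for m in c.members:
        if m.basal_k27ac is None:
            label = m.name or f"{m.interval.chrom}:{m.interval.start}-{m.interval.end}"
            raise ValueError(f"member {label} of {c.cluster_id} lacks a basal_k27ac flag")
    ere = [bool(m.has_full_ere) for m in c.members]
    k27 = [bool(m.basal_k27ac) for m in c.members]
    n_ere, n_k27 = sum(ere), sum(k27)
    mmp17 = any(e and k for e, k in zip(ere, k27))
    cish = any(
        ere[i] and k27[j]
        for i in range(len(ere))
        for j in range(len(k27))
        if i != j
    )
    return ClusterClassification(
        cluster_id=c.cluster_id,
        size=c.size,
        n_full_ere_members=n_ere,
        n_basal_k27ac_members=n_k27,
        active=n_ere >= 1 and n_k27 >= 1,
        mmp17_like=mmp17,
        cish_like=cish,
    )


def classify_clusters(clusters: Iterable[Cluster]) -> dict[str, ClusterClassification]:
    return {c.cluster_id: classify_cluster(c) for c in clusters}


@dataclass(frozen=True)
class ClassificationCensus:
    """Counts and fractions of active clusters by architecture.

    Subtype fractions use active clusters as denominator and are ``None`` when
    there are no active clusters (undefined, not zero). Two denominators are
    reported for the MMP17-like fraction: all active clusters, and active
    clusters within an up-regulated gene's window (when annotations are
    supplied). Per-gene counts among up-regulated genes report the
    MMP17-only / CISH-only split plus both readings of "both types": genes
    whose window holds clusters of both kinds anywhere (``n_up_both_any``) and
    genes with at least one single dual-qualifying cluster
    (``n_up_both_single_cluster``).
    """

    n_clusters: int
    n_active: int
    n_mmp17_like: int
    n_cish_like: int
    frac_mmp17_of_active: float | None
    frac_cish_of_active: float | None
    frac_mmp17_of_active_near_up: float | None = None
    n_up_mmp17_only: int | None = None
    n_up_cish_only: int | None = None
    n_up_both_any: int | None = None
    n_up_both_single_cluster: int | None = None


def classification_census(
    classifications: Mapping[str, ClusterClassification],
    annotations: Sequence | None = None,
    genes: Sequence | None = None,
) -> ClassificationCensus:
    """Summarize subtype composition, optionally per up-regulated gene.

    ``annotations`` are per-gene cluster annotations (from the gene linker)
    and ``genes`` the matching gene records; both are needed for the
    gene-level counts.
    """
    cls = list(classifications.values())
    n_active = sum(c.active for c in cls)
    n_mmp17 = sum(c.mmp17_like for c in cls)
    n_cish = sum(c.cish_like for c in cls)
    frac_mmp17 = n_mmp17 / n_active if n_active else None
    frac_cish = n_cish / n_active if n_active else None

    frac_near_up = None
    up_counts: dict[str, int | None] = {
        "mmp17_only": None, "cish_only": None, "both_any": None, "both_single": None
    }
    if annotations is not None and genes is not None:
        reg = {g.gene_id: g.reg_class for g in genes}
        near_up_ids: set[str] = set()
        counts = {"mmp17_only": 0, "cish_only": 0, "both_any": 0, "both_single": 0}
        for ann in annotations:
            if reg.get(ann.gene_id) != "up":
                continue
            near_up_ids.update(ann.clusters_in_window)
            has_m = bool(ann.has_mmp17_like)
            has_c = bool(ann.has_cish_like)
            if has_m and has_c:
                counts["both_any"] += 1
            elif has_m:
                counts["mmp17_only"] += 1
            elif has_c:
                counts["cish_only"] += 1
            if any(
                classifications[cid].mmp17_like and classifications[cid].cish_like
                for cid in ann.clusters_in_window
                if cid in classifications
            ):
                counts["both_single"] += 1
        active_near_up = [classifications[cid] for cid in near_up_ids
                          if cid in classifications and classifications[cid].active]
        if active_near_up:
            frac_near_up = sum(c.mmp17_like for c in active_near_up) / len(active_near_up)
        up_counts = counts  # type: ignore[assignment]

    return ClassificationCensus(
        n_clusters=len(cls),
        n_active=n_active,
        n_mmp17_like=n_mmp17,
        n_cish_like=n_cish,
        frac_mmp17_of_active=frac_mmp17,
        frac_cish_of_active=frac_cish,
        frac_mmp17_of_active_near_up=frac_near_up,
        n_up_mmp17_only=up_counts["mmp17_only"],
        n_up_cish_only=up_counts["cish_only"],
        n_up_both_any=up_counts["both_any"],
        n_up_both_single_cluster=up_counts["both_single"],
    )
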