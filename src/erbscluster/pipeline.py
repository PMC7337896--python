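"""End-to-end orchestration: annotate -> mark K27ac -> cluster -> classify ->
link genes -> enrichment statistics.

`run_stages` drives the analysis on in-memory objects (the route the
simulation studies use); `run_all` is the file-based wrapper that reads a
:class:`RunConfig`, validates every input up front, writes each stage's table
and a run manifest, and is byte-deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import activity as act
from . import clustering as clu
from . import genes as gn
from . import motifs as mot
from . import stats as st
from .intervals import GenomicInterval, IntervalSet
from .io import FastaGenome, GeneRecord, Genome, read_bed, read_gene_table, write_bed

logger = logging.getLogger("erbscluster")

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_stages",
    "run_all",
    "write_annotated_sites",
    "read_annotated_sites",
    "write_classifications",
    "write_gene_annotations",
]


@dataclass
class RunConfig:
    """Resolved configuration of one full pipeline run."""

    sites_bed: str
    genome_fasta: str
    k27ac_bed: str
    genes_tsv: str
    out_dir: str
    controls: dict[str, str] = field(default_factory=dict)
    gap: int = 10_000
    radius: int = 100_000
    max_mismatch: int = 2
    test: str = "ranksum"
    distance_mode: str = "edge"
    n_control_seeds: int = 10
    seed: int = 7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.test not in ("ranksum", "signedrank"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.distance_mode not in ("edge", "midpoint"):
            raise ValueError(f"unknown distance mode {self.distance_mode!r}")
        paths = [self.sites_bed, self.genome_fasta, self.k27ac_bed, self.genes_tsv]
        paths += list(self.controls.values())
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


@dataclass
class PipelineResult:
    """Everything one pipeline run computed, stage by stage."""

    records: list[mot.ErbsRecord]
    clusters: list[clu.Cluster]
    classifications: dict[str, act.ClusterClassification]
    annotations: list[gn.GeneClusterAnnotation]
    summary: clu.ClusteringSummary
    control_summaries: list[clu.ControlSummary]
    proportions: pd.DataFrame
    census: act.ClassificationCensus
    fisher_table: st.ContingencyTable2x2
    fisher: st.TestResult
    foldchange_groups: gn.FoldChangeGroups
    foldchange_test: st.TestResult | None
    run_id: str | None = None


def _paired_signed_rank(
    x: np.ndarray, y: np.ndarray, seed: int, tails: str = "two-sided"
) -> st.TestResult:
    """Signed-rank variant for two unpaired groups.

    Pairs order statistics after seeded down-sampling of the larger group to
    the smaller group's size; provided to mirror an analysis that applies the
    paired test to independent gene groups. The rank-sum test is the
    statistically appropriate default.
    """
    rng = np.random.default_rng(seed)
    n = min(x.size, y.size)
    xs = np.sort(rng.choice(x, size=n, replace=False)) if x.size > n else np.sort(x)
    ys = np.sort(rng.choice(y, size=n, replace=False)) if y.size > n else np.sort(y)
    return st.wilcoxon_signed_rank(xs - ys, tails=tails)


def run_stages(
    sites: IntervalSet,
    genome: Genome,
    k27_peaks: IntervalSet,
    genes: Sequence[GeneRecord],
    controls: Mapping[str, IntervalSet] | None = None,
    *,
    gap: int = 10_000,
    radius: int = 100_000,
    max_mismatch: int = 2,
    test: str = "ranksum",
    distance_mode: str = "edge",
    n_control_seeds: int = 10,
    seed: int = 7,
    run_id: str | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs and return every stage output."""
    model = mot.EreModel(max_mismatch=max_mismatch)
    records = mot.annotate_erbs(sites, genome, model)
    logger.info("annotate: %d sites, %d with full ERE",
                len(records), sum(r.has_full_ere for r in records))
    records = act.mark_basal_k27ac(records, k27_peaks)
    clusters = clu.build_clusters(records, gap)
    classifications = act.classify_clusters(clusters)
    logger.info("cluster: %d clusters, %d active",
                len(clusters), sum(c.active for c in classifications.values()))
    summary = clu.clustering_summary(sites, gap, mode=distance_mode)
    control_summaries: list[clu.ControlSummary] = []
    if controls:
        seeds = [seed + k for k in range(n_control_seeds)]
        control_summaries = clu.control_comparison(
            controls, n=len(sites), seeds=seeds, gap=gap, mode=distance_mode
        )
    annotations = gn.assign_clusters_to_genes(clusters, genes, radius, classifications)
    proportions = gn.class_proportions(annotations, genes)
    census = act.classification_census(classifications, annotations, genes)

    ann_by_gene = {a.gene_id: a for a in annotations}
    a = b = c = d = 0
    for g in genes:
        has_active = ann_by_gene[g.gene_id].has_active_cluster
        if g.reg_class == "up":
            a += has_active
            b += not has_active
        else:
            c += has_active
            d += not has_active
    fisher_table = st.ContingencyTable2x2(a, b, c, d)
    fisher = st.fisher_exact(fisher_table, tails="two-sided")

    groups = gn.foldchange_partition(annotations, genes, "active_cluster")
    fc_test: st.TestResult | None = None
    if groups.with_feature.size and groups.without_feature.size:
        if test == "ranksum":
            fc_test = st.wilcoxon_rank_sum(
                groups.with_feature, groups.without_feature, tails="two-sided"
            )
        elif test == "signedrank":
            fc_test = _paired_signed_rank(
                groups.with_feature, groups.without_feature, seed
            )
        else:
            raise ValueError(f"unknown test {test!r}")
    logger.info("stats: fisher p=%.3g OR=%.3g; foldchange p=%s",
                fisher.p_value, fisher.odds_ratio or float("nan"),
                f"{fc_test.p_value:.3g}" if fc_test else "NA")
    return PipelineResult(
        records=records,
        clusters=clusters,
        classifications=classifications,
        annotations=annotations,
        summary=summary,
        control_summaries=control_summaries,
        proportions=proportions,
        census=census,
        fisher_table=fisher_table,
        fisher=fisher,
        foldchange_groups=groups,
        foldchange_test=fc_test,
        run_id=run_id,
    )


# ---------------------------------------------------------------------------
# stage tables
# ---------------------------------------------------------------------------

_SITE_COLUMNS = ["chrom", "start", "end", "name", "has_full_ere",
                 "best_full_mismatches", "n_half_sites", "basal_k27ac"]


def write_annotated_sites(records: Sequence[mot.ErbsRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(dict(
            chrom=r.interval.chrom, start=r.interval.start, end=r.interval.end,
            name=r.name or ".",
            has_full_ere=int(r.has_full_ere),
            best_full_mismatches="." if r.best_full_mismatches is None else r.best_full_mismatches,
            basal_k27ac="." if r.basal_k27ac is None else int(r.basal_k27ac),
            n_half_sites=r.n_half_sites,
        ))
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotated_sites(path: str | Path) -> list[mot.ErbsRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for row in df.itertuples():
        has_full = bool(int(row.has_full_ere))
        records.append(mot.ErbsRecord(
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end),
                                     None if row.name == "." else row.name),
            has_full_ere=has_full,
            best_full_mismatches=int(row.best_full_mismatches) if has_full else None,
            n_half_sites=int(row.n_half_sites),
            basal_k27ac=None if row.basal_k27ac == "." else bool(int(row.basal_k27ac)),
        ))
    return records


def write_classifications(
    classifications: Mapping[str, act.ClusterClassification], path: str | Path
) -> None:
    rows = [asdict(c) for c in classifications.values()]
    cols = ["cluster_id", "size", "n_full_ere_members", "n_basal_k27ac_members",
            "active", "mmp17_like", "cish_like"]
    df = pd.DataFrame(rows, columns=cols)
    for col in ("active", "mmp17_like", "cish_like"):
        df[col] = df[col].astype(int)
    df.to_csv(path, sep="\t", index=False)


def write_gene_annotations(
    annotations: Sequence[gn.GeneClusterAnnotation], path: str | Path
) -> None:
    rows = []
    for a in annotations:
        rows.append(dict(
            gene_id=a.gene_id,
            clusters_in_window=",".join(a.clusters_in_window) or ".",
            n_clusters=len(a.clusters_in_window),
            has_multi_cluster=int(a.has_multi_cluster),
            has_active_cluster=int(a.has_active_cluster),
            has_inactive_only=int(a.has_inactive_only),
            has_mmp17_like=int(a.has_mmp17_like),
            has_cish_like=int(a.has_cish_like),
        ))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """File-based full run: validate, execute, write stage outputs + manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # fail-fast: parse every input before any stage runs
    sites = read_bed(cfg.sites_bed)
    if len(sites) == 0:
        raise ValueError(f"{cfg.sites_bed}: no sites")
    genome = FastaGenome(cfg.genome_fasta)
    k27 = read_bed(cfg.k27ac_bed)
    genes = read_gene_table(cfg.genes_tsv)
    if not genes:
        raise ValueError(f"{cfg.genes_tsv}: gene table is empty")
    controls = {name: read_bed(p) for name, p in cfg.controls.items()}
    for name, cset in controls.items():
        if len(cset) < len(sites):
            raise ValueError(
                f"control {name!r} has {len(cset)} sites, fewer than {len(sites)} ERBS"
            )

    result = run_stages(
        sites, genome, k27, genes, controls,
        gap=cfg.gap, radius=cfg.radius, max_mismatch=cfg.max_mismatch,
        test=cfg.test, distance_mode=cfg.distance_mode,
        n_control_seeds=cfg.n_control_seeds, seed=cfg.seed,
    )

    write_annotated_sites(result.records, out / "annotated_sites.tsv")
    cluster_bed = IntervalSet(
        [GenomicInterval(c.span.chrom, c.span.start, c.span.end,
                         name=f"{c.cluster_id};size={c.size}")
         for c in result.clusters],
        is_sorted=True,
    )
    write_bed(cluster_bed, out / "clusters.bed")
    write_classifications(result.classifications, out / "cluster_classifications.tsv")
    active_bed = IntervalSet([
        GenomicInterval(
            c.span.chrom, c.span.start, c.span.end,
            name=f"{c.cluster_id};{_subtype_label(result.classifications[c.cluster_id])}",
        )
        for c in result.clusters
        if result.classifications[c.cluster_id].active
    ], is_sorted=True)
    write_bed(active_bed, out / "active_clusters.bed")
    write_gene_annotations(result.annotations, out / "gene_annotations.tsv")
    result.proportions.to_csv(out / "class_proportions.tsv", sep="\t")
    # the observed summary alongside the subsampled-control summaries
    rows = [asdict(result.summary) | dict(set="erbs", seed=cfg.seed)]
    rows += [asdict(cs.summary) | dict(set=cs.control, seed=cs.seed)
             for cs in result.control_summaries]
    pd.DataFrame(rows).to_csv(out / "clustering_summaries.tsv", sep="\t", index=False)
    clu.distance_histogram(sites, mode=cfg.distance_mode).to_csv(
        out / "neighbor_distance_histogram.tsv", sep="\t", index=False
    )

    stats_rows = [dict(
        comparison="active_cluster_vs_up_regulation",
        method=result.fisher.method, p_value=result.fisher.p_value,
        odds_ratio=result.fisher.odds_ratio,
        table=f"{result.fisher_table.a},{result.fisher_table.b},"
              f"{result.fisher_table.c},{result.fisher_table.d}",
    )]
    if result.foldchange_test is not None:
        stats_rows.append(dict(
            comparison="log2fc_up_genes_by_active_cluster",
            method=result.foldchange_test.method,
            p_value=result.foldchange_test.p_value,
            odds_ratio="", table="",
        ))
    pd.DataFrame(stats_rows).to_csv(out / "stats.tsv", sep="\t", index=False)
    census_payload = {k: v for k, v in asdict(result.census).items()}
    (out / "census.json").write_text(json.dumps(census_payload, indent=2, sort_keys=True) + "\n")

    resolved = asdict(cfg)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    manifest = dict(
        config=resolved,
        inputs={p: _md5(p) for p in [cfg.sites_bed, cfg.genome_fasta, cfg.k27ac_bed,
                                     cfg.genes_tsv, *cfg.controls.values()]},
        counts=dict(
            sites=len(sites),
            clusters=len(result.clusters),
            active_clusters=sum(c.active for c in result.classifications.values()),
            genes=len(genes),
            control_summaries=len(result.control_summaries),
        ),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("run-all complete: %d clusters from %d sites", len(result.clusters), len(sites))
    return manifest


def _subtype_label(c: act.ClusterClassification) -> str:
    if c.mmp17_like and c.cish_like:
        return "mmp17+cish"
    if c.mmp17_like:
        return "mmp17"
    return "cish"
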