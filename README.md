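# erbscluster

Genome-wide analysis of estrogen receptor binding-site (ERBS) clusters:
interval clustering, estrogen response element (ERE) motif annotation,
enhancer-activity classification, gene association through TSS windows, and
the enrichment statistics that tie clusters to estrogen-driven gene
expression — plus a synthetic-landscape generator so the whole pipeline is
testable without any external data.

## Who this is for

Regulatory genomicists studying how neighboring ER-bound enhancers cooperate.
Starting from standard inputs — BED/narrowPeak files of ER binding sites and
basal (vehicle-condition) H3K27ac peaks, a genome FASTA, control site sets,
and a gene table with one TSS and one estrogen-regulation call per gene —
the package answers:

* Do binding sites cluster more than matched control regions? Sites within
  10 kb are merged into clusters (`bedtools merge` semantics) and compared
  with randomly subsampled control sets.
* Which clusters are *active*? A cluster is active when it contains at least
  one **full ERE** (the palindromic consensus `AGGTCAnnnTGACCT`, up to 2
  mismatches over the 12 constrained positions) **and** at least one site
  overlapping basal H3K27ac. Active clusters are *hierarchical*
  (MMP17-like: one site carries both features) or *synergistic* (CISH-like:
  the features sit on different sites).
* Are active clusters enriched near estrogen-up-regulated genes, and do
  those genes respond more strongly? Clusters are assigned to genes through
  ±100 kb TSS windows; enrichment uses Fisher's exact test with the sample
  odds ratio (a·d)/(b·c), and fold-change comparisons use Wilcoxon rank
  tests.

See `docs/methods.md` for the full model, parameter rationale and numerical
conventions.

## Worked example

Everything below is reproducible; the numbers are what the commands print.

```python
from erbscluster.simulate import SimConfig, simulate
from erbscluster.pipeline import run_stages

bundle = simulate(SimConfig(seed=1))          # 3000 sites, 2000 genes, 4x150 Mb
result = run_stages(bundle.sites, bundle.genome, bundle.k27_peaks,
                    bundle.genes, bundle.controls, n_control_seeds=5, seed=1)

print(result.summary)
# ClusteringSummary(n_sites=3000, n_clusters=2256, n_multi_clusters=699,
#                   frac_sites_with_neighbor=0.481, frac_multi_windows=0.3098404255319149)

print(result.fisher_table, round(result.fisher.odds_ratio, 2))
# ContingencyTable2x2(a=84, b=216, c=161, d=1539) 3.72
print(f"{result.fisher.p_value:.2e}", f"{result.foldchange_test.p_value:.2e}")
# 3.15e-16 6.66e-05
```

Reading: 48% of the simulated sites have a neighbor within 10 kb and 31% of
merged windows hold more than one site (the subsampled uniform controls give
~5%), because the generator plants 40% of sites as close pairs. 84 of 300
up-regulated genes versus 161 of 1700 other genes have an active cluster
within 100 kb of the TSS — an odds ratio of 3.7 (Fisher p = 3.2e-16) — and
up-regulated genes with an active cluster nearby show larger log2 fold
changes (rank-sum p = 6.7e-05), recovering the planted coupling.

The same analysis runs from files:

```bash
erbs simulate --out-dir sim/ --seed 1 --config small.yaml   # writes FASTA/BED/TSV + truth
erbs run-all --config run.yaml                              # annotate -> cluster -> classify -> link -> enrich
```

where `run.yaml` points at the input files and an output directory. Each
stage is also a standalone subcommand (`erbs annotate|cluster|classify|link|
enrich`) operating on the standard formats, so intermediate tables can be
inspected or regenerated individually. Reruns with the same config are
byte-identical.

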