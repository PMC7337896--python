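# Methods

## The analysis

`erbscluster` re-implements a genome-wide characterisation of estrogen
receptor alpha (ER) binding-site (ERBS) clusters in a reusable form. The
analysis chain is:

1. **ERE annotation.** Every binding-site interval is scanned for the
   estrogen response element. The full ERE is modelled as the palindromic
   consensus `AGGTCAnnnTGACCT`: two AGGTCA hexamers in inverted orientation
   around an unconstrained 3-bp spacer. A window is a *full ERE* when at most
   `max_mismatch` (default 2) of its 12 constrained positions differ from the
   consensus; spacer positions never count, and `N` always counts as a
   mismatch. Because the constrained consensus is its own reverse complement,
   one forward scan covers both strands and each matching window is reported
   once. *Half EREs* are exact AGGTCA matches on either strand; half hits
   inside a reported full-ERE window are excluded from the half-site count,
   so a perfect palindrome is not also counted as two half-sites. The
   mismatch rule is the single motif definition (no position-weight-matrix
   mode); the threshold is configurable because the boundary between a
   "strong" and a degenerate ERE is a judgement call — mouse genetics places
   the functional boundary at 1–2 mismatches from consensus, which motivates
   the default. The whole peak interval is scanned rather than a fixed
   summit-centred core, since functional enhancer cores are of the same
   order as peak widths (~125–225 bp).

2. **Basal H3K27ac marking.** A site is acetylated at baseline when it
   overlaps (>= 1 bp, half-open BED semantics) a vehicle-condition H3K27ac
   peak.

3. **Clustering.** Sites whose edge-to-edge distance is at most *d* = 10 kb
   are merged into clusters (the semantics of `bedtools merge -d`), i.e.
   clusters are connected components of the "gap <= d" relation per
   chromosome. The equivalent description "assign each site a +/-10 kb window
   and merge overlapping windows" corresponds to midpoint distances at 20 kb;
   edge-merge at 10 kb is the default and a midpoint mode is available.
   Nearest-neighbor distances default to edge-to-edge gaps (0 for
   overlapping peaks); summit-to-summit distances are obtained by passing
   summit point intervals or the midpoint mode.

4. **Activity classification.** A cluster is *active* when it contains at
   least one full-ERE site and at least one basally acetylated site. Active
   clusters are *hierarchical* (MMP17-like) when one member carries both
   features, and *synergistic* (CISH-like) when the ERE-bearer and the
   acetylated member are distinct sites (i != j). A cluster of three or more
   members can be both; singletons are classifiable (a dual-feature
   singleton is MMP17-like). The subtype census reports fractions over all
   active clusters and over active clusters near up-regulated genes, because
   the appropriate denominator is ambiguous; the per-gene "both subtypes"
   count is likewise reported both as "both flags anywhere in the window"
   and "at least one dual-qualifying cluster".

5. **Gene linkage.** A cluster belongs to a gene when its span overlaps the
   +/-100 kb window around the gene's single annotated TSS. Window-overlap
   (not midpoint containment) was chosen as the most literal reading of
   "within 100 kb of the TSS"; partial overlap at the window edge counts.
   All three regulation classes (up / down / not) are annotated so the
   active / inactive-only / no-cluster partition — mutually exclusive and
   exhaustive per gene — is computable for each class.

6. **Statistics.** Enrichment of active clusters near up-regulated genes
   uses Fisher's exact test on the 2x2 table (up vs other genes x active
   cluster present/absent) with the sample odds ratio (a·d)/(b·c) and a
   Woolf (log) confidence interval (Haldane-Anscombe 0.5 correction with any
   zero cell). Two-sided extremeness is probability-based. The fold-change
   comparison between up-regulated genes with and without a nearby active
   cluster defaults to the unpaired Wilcoxon rank-sum test, since the two
   gene groups are independent. A signed-rank variant is selectable: it
   pairs order statistics after seeded down-sampling of the larger group,
   mirroring analyses that name the signed-rank test for such comparisons;
   it is never substituted silently. Exact enumeration is used for small
   tie-free samples (rank-sum: <= 12 pooled observations; signed-rank: <= 15
   nonzero differences), a tie- and continuity-corrected normal
   approximation otherwise. No multiple-testing correction is applied (each
   run reports single planned tests).

Control comparisons subsample *n* = |ERBS| intervals without replacement
from larger control region sets (uniform stand-ins for DNase-hypersensitive
or CTCF sites) and re-run the identical cluster analysis, one summary per
seed. Controls are not deduplicated before subsampling.

## Coordinate and randomness conventions

All coordinates are 0-based half-open (BED); readers convert on ingest,
writers on output. `[a,b)` and `[b,c)` do not overlap; book-ended intervals
merge at any gap >= 0. Window clipping is at 0 on the left and, when a
chromosome-length table is supplied, at the chromosome end on the right.
Every stochastic operation takes an explicit seed; the pipeline derives
control-subsampling seeds as `seed + k`.

## The synthetic-data generator

The generator (`erbscluster.simulate`) emulates the statistical structure
the analysis assumes — not read-level data. Defaults are a desk-scale
analogue of the study system, chosen once:

| parameter | default | rationale |
| --- | --- | --- |
| genome | 4 x 150 Mb | one gene per 300 kb, matching human gene density per TSS window |
| `n_sites` | 3000 | same order as a genome-wide ER peak set after scaling |
| `site_width` | 200 bp | typical ChIP-seq peak core |
| `f_pair` | 0.4 | fraction of sites placed as <= 10 kb neighbor pairs; reproduces the reported ~40% close-neighbor excess |
| `pair_gap_max` | 10 kb | pair gaps ~ Uniform(0.4, 10 kb), mass below the merge distance |
| `p_full_ere` / `p_basal_k27ac` / `p_half_ere` | 0.3 / 0.25 / 0.3 | independent per-site feature probabilities for background sites |
| planted ERE mismatches | Uniform{0,1,2} | spans the tolerated range |
| `pi_active` / `pi_baseline` | 0.28 / 0.09 | probability an up- (other-) regulated gene is coupled to an active cluster within 100 kb, matching the reported class proportions |
| `fc_base_mean`, `fc_sd`, `fc_shift` | 1.0, 0.8, 0.5 | log2 units; coupled up-genes are shifted by `fc_shift` |
| `subtype_mmp17` | 0.8 | planted hierarchical:synergistic mixture |
| `n_control_sites` | 12000 per set | control sets severalfold larger than the site set |

Genome sequence is uniform i.i.d. ACGT served block-wise by a counter-based
(Philox) generator keyed by (seed, chromosome, block), so arbitrary slices —
and hence arbitrarily large chromosomes — are reproducible without
materialising the genome; FASTA export materialises on demand. Site
sequences are explicit overrides: backgrounds are redrawn until they contain
no chance full ERE (nor chance exact half-site), the planted motif is
written in, and the site is rescanned to confirm the realized hit set equals
the planted truth exactly. This makes planted-motif recovery an exact
property rather than a statistical one.

Coupling is enforced by construction. Per-gene coupling flags are drawn
first (Bernoulli with `pi_active` or `pi_baseline`). Windows of uncoupled
genes, dilated by the merge distance plus the maximal planted-cluster
extent, are forbidden zones: planted clusters and any background site
combination that would form an active cluster are placed outside them, and
background sites never come within the merge distance of planted sites or
of complementary-feature background sites, so merge chains cannot create an
active cluster next to an uncoupled gene. A coupled gene whose window is
fully blocked or too crowded has its TSS resampled; as a last resort its
flag flips to uncoupled (recorded in the truth table, warned about, and
essentially absent at default scale). The one residual leak is a merge
chain running through feature-less sites (expected well below one event per
default-size run). Consequently the planted per-gene truth is exact, which
is what makes odds-ratio coverage of the planted odds a meaningful
end-to-end property.

Sites are non-overlapping with a minimum separation of one K27ac peak width
(400 bp), so no site overlaps a neighboring site's attached acetylation
peak. Attached K27ac peaks are centred on their site with width
2 x `site_width`; background K27ac peaks are placed uniformly away from all
sites. Control sets are uniform i.i.d. intervals.

What the generator does **not** emulate: realistic sequence composition
(GC content, repeats), peak-shape or read-level noise, multi-TSS genes,
distance-dependent enhancer-promoter weighting, and correlated chromatin
domains. Passing tests therefore demonstrate correctness of the algorithms
and the statistical machinery under the assumed structure, not robustness
to every property of real ChIP-seq data.

## Numerical choices and degenerate inputs

* Merge gap comparison is inclusive (`gap <= d`); output clusters are
  separated by gaps strictly greater than d.
* Intervals alone on their chromosome have no neighbor distance; they are
  omitted from distance lists and counted separately, and they count as
  "no neighbor" in `frac_sites_with_neighbor` (denominator: all sites).
* Subtype fractions with zero active clusters are reported as undefined
  (None/NA), never 0.
* An all-zero difference vector or an empty group is an error for the rank
  tests, not a p-value.
* The sample odds ratio is infinite when b·c = 0 with a·d > 0 and NaN on a
  zero margin.
* Simulation problem sizes used by the test suite: oracle equivalence on
  500 randomized instances (up to 300 intervals), 100 motif genomes of
  150 kb, 10,000 null replicates for test calibration, and 100 + 100
  simulated cohorts (3000 sites, 2000 genes) for coupling recovery — sizes
  at which every check is stable yet the whole suite stays fast.

## Known limitations

* The gene table carries exactly one TSS per gene; collapsing multi-TSS
  annotations is delegated to data preparation (the GTF importer takes the
  strand-aware 5'-most transcript start).
* No PWM/FIMO-style scoring, no variable ERE spacer, no non-ER motif
  discovery, and no shuffle-based placement nulls (the control model is
  subsampling of real or simulated control region sets).
* The activity classification is feature-based; it does not model the
  mechanistic hierarchy (ER recruitment order, acetylation spreading)
  that motivates the MMP17/CISH terminology.
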