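# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `consnet`. Everything quantitative stated here is
recomputed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory.

## Pipeline model and assumptions

The pipeline assumes a study of k ≥ 2 independent bulk RNA-seq datasets per
tissue region, each with the same two condition groups and a shared gene
universe. Stages:

1. **Expression filter.** A gene is kept when it reaches ≥ `cpm_min`
   (default 1) counts per million in ≥ `cpm_frac` (default 0.7) of samples;
   both boundaries inclusive. CPM avoids favoring genes in larger
   libraries. The filter is idempotent.
2. **Normalization.** Median-of-ratios size factors: per sample, the median
   over genes expressed in every sample of count / per-gene geometric mean
   (real-space median; for an even reference-gene count this is the
   arithmetic mean of the middle two ratios). Normalization is
   rank-preserving within a sample and errors clearly when no gene is
   expressed everywhere.
3. **Signed wTO.** Pearson correlation on log2(normalized + 1) (the scale
   is configurable via `log_transform`), then the signed weighted
   topological overlap with denominator `min(k_i, k_j) + 1 − |a_ij|`,
   `k_i = Σ_{u≠i} |a_iu|`. The denominator is ≥ 1 whenever |a| ≤ 1, so the
   operation has no singular inputs; |w| ≤ 1 always (property-tested).
   Links with |w| < `wto_cutoff` (default 0.5) are discarded — the stated
   "< cutoff discarded" convention means the boundary value is retained.
   Matrices are dense float64 with a hard cap of 6 000 genes; the intended
   scale is a few thousand genes, and a clear error beats silent chunking.
4. **Consensus.** Intersection of the per-dataset thresholded networks
   (filter first, then integrate), sign-discordant links excluded, and the
   magnitude-weighted average Ω as the consensus weight. Ω is a convex
   combination: bounded by the input extremes, equal to the simple mean iff
   all magnitudes agree, and |Ω| ≥ |mean| for same-sign inputs. Exact zero
   weights are sign-neutral and excluded (α would be 0/0).
5. **Differential links.** Presence means |Ω| ≥ `diff_cutoff` (default
   0.33, boundary inclusive). Genes missing from one condition's network
   are added with zero-weight links so their links classify as
   condition-specific rather than silently vanishing. The four categories
   partition the union; classifying a network against itself yields 100 %
   conserved, and swapping conditions swaps the specific labels.
6. **Topology.** Coreness by iterative peeling (weights ignored); hubs are
   exactly the innermost shell, with no top-N fallback. Louvain communities
   on the unweighted graph at resolution 1 (signed weights cannot enter the
   modularity objective); clusters with fewer than `min_cluster_links`
   (default 20) internal links are dropped. Louvain is order-dependent, so
   the partition is computed under a fixed seed and validated by modularity
   non-regression and planted-truth recovery rather than an exact expected
   partition.
7. **Enrichment.** One-sided hypergeometric over-representation per
   (cluster, category) over the protein-coding background that entered
   network construction; BH correction across terms within each cluster;
   categories with fewer than `min_term_size` (default 5) background genes
   are excluded. Only protein-coding genes are tested.
8. **RWR annotation.** Fixed point of `p ← (1 − r) W p + r p0` with
   `r = rwr_restart` (default 0.7), W the column-normalized *binary*
   adjacency of the cluster subgraph, p0 uniform over the enriched
   category's protein-coding members. Scores from power iteration agree
   with the direct linear solve to ≤ 1e−8 on 50-node graphs (tested).
   LncRNAs at or above the `assign_percentile`-th percentile (default 90,
   ties included) of the cluster's lncRNA scores are eligible; acceptance
   additionally requires the score to be ≥ the minimum leave-one-out score
   of the category's own members. The percentile is computed over the
   cluster's lncRNAs only (they are what is being ranked); both the
   percentile and the restart probability are configuration knobs.
9. **Evaluation.** Szymkiewicz–Simpson coefficient |A∩B| / min(|A|, |B|);
   permutation test drawing size-matched sets from each network's lncRNA
   pool without replacement (`n_perm` default 10 000 — the analysis this
   mirrors reports both 10 000 and 1 000, so it is a parameter), reporting
   the proportion of permuted coefficients ≥ observed, or the bound
   "< 1/n_perm" at zero exceedances. Fisher's exact test (two-sided,
   minimum-likelihood convention) with the cross-product odds ratio for
   core lncRNA composition.

### Numerical conventions

- RWR convergence: L1 tolerance 1e−10, max 100 000 iterations; probability
  mass on degree-zero nodes teleports fully back to the seed distribution,
  keeping the iteration stochastic. `r = 1` returns p0 exactly.
- Differential expression (stand-in engine): Welch's t-test on
  log2(normalized + 1) with BH correction; log2 fold change uses a 0.5
  pseudocount on group means; a gene with zero variance in both groups gets
  p = 1 and a `degenerate` flag. Thresholds FDR < 0.05 **and**
  |log2FC| > 0.3 are conjunctive; the fold-change threshold is interpreted
  on the log2 scale (configurable). The pipeline's substantive rule is the
  *intersection*: a consensus DEG must be significant with a consistent
  direction in every contributing dataset.
- Edge tables are canonical (node1 < node2 lexicographically) everywhere;
  readers re-canonicalize and reject self-loops.
- Config objects round-trip through YAML and stamp a SHA-256 prefix on all
  outputs.

## The synthetic-study generator

`synthdata.generate_study` emulates the target design: `n_datasets_per_condition`
independent datasets (default 3), two conditions, `n_samples` per dataset
per condition (default 40), `n_genes` (default 300) of which four modules
of 70 carry latent structure and ~15 % are lncRNAs.

Per module and (dataset, condition), a latent eigengene is drawn across
samples; gene g in the module has loading ±√`within_module_cor`
(default magnitude √0.9, 25 % negative to plant signed links); the
log-mean is `base_g + latent_scale · (l_g E + √(1−l_g²) ε)` with
`latent_scale = 1.5` and gene baselines `N(6.5, 1)` on the natural-log
scale; counts are negative-binomial (gamma–Poisson) with dispersion 0.08
and log-normal library-size factors (σ = 0.2). Rewired modules (default
fraction 0.25) split in condition B into kept, sign-flipped and detached
thirds, planting conserved, reversed and condition-specific links
respectively. Protein-coding members of each module define that module's
functional category; the module's lncRNAs are the recorded assignment
truth. `plant_differential_expression` scales a gene's counts by
2^effect with stochastic rounding, which scales the mean exactly and
leaves the dispersion unchanged.

Three generator choices were calibrated at design time so that planted
structure survives the fixed |w| ≥ 0.5 analysis cutoff at this scale, and
then frozen:

- **Module size 70 in a 300-gene universe.** The wTO denominator
  accumulates ~Σ|noise correlations| from all non-module genes; with
  40-gene modules that background term pushed within-module weights below
  the cutoff. Larger modules raise the shared-neighbor numerator linearly.
- **In-sample orthogonal eigengenes.** With iid eigengenes, chance
  correlations between modules (sd 1/√n_samples) leak into every member
  pair's denominator and preferentially erode mixed-sign links, splitting
  modules along loading signs. Eigengenes are therefore drawn mutually
  orthogonal within each dataset (QR of a Gaussian matrix). Real
  co-expression modules are *not* orthogonal — this is a deliberate
  simplification that isolates the planted signal.
- **Baseline e^6.5, amplitude 1.5.** At lower baselines the zero floor of
  counts censors antithetic (negative-correlation) pairs more strongly
  than concordant ones, biasing signed links.

What the generator does **not** emulate: gene-length effects, GC bias,
batch structure within a dataset, overlapping or hierarchically nested
modules, hub-dominated scale-free topology within modules, condition
effects on library size, and cell-type mixture shifts. Passing
planted-recovery tests therefore demonstrates the pipeline's correctness
and statistical behavior under its own model, not performance on real
cohort data.

## Study-scale choices

Default problem sizes (300 genes, 3+3 datasets × 40 samples, 1 000
permutations in tests, 10 000 by default in production configs) keep a full
pipeline run at a few seconds and the entire test suite under a minute
while leaving every stage's statistics well-resolved. The dense-matrix cap
and the generator's scale are the package's intended operating envelope;
genome-scale inputs should be pre-filtered (the expression filter plus
variance ranking typically reduces a cohort to a few thousand genes).

## Known limitations

- The DE engine is deliberately a Welch-t stand-in, not a negative-binomial
  GLM; dispersion shrinkage across genes is out of scope. Fold-change and
  FDR thresholds are faithful, and the cross-dataset intersection rule is
  exact.
- The differential-link classifier implements the three published category
  definitions directly; it does not reproduce any particular package's
  internal weight re-normalization.
- Louvain partitions are seed-dependent on near-degenerate modularity
  landscapes; only seed-fixed determinism is guaranteed.
- Permutation p-values are discrete and therefore super-uniform under the
  null (conservative); zero exceedances are reported as a bound, not as 0.
- Cross-region integration is intentionally unsupported: consensus networks
  are only built within a region, and comparisons across regions go through
  the overlap statistics.
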