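# Methods

This note documents the models and procedures implemented in `metaltrait`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Inventory construction

Domain-hit tables are consumed in a BLAST-tabular ("outfmt 6"-like) dialect
with two extension columns, `hit_class` ∈ {specific, superfamily,
nonspecific} and `family_label`. The genome id comes from a
`genome|protein` query-id prefix or an explicit protein→genome mapping.
Hits are ranked per query by descending bitscore (ties: ascending e-value,
then lexicographic model id — deterministic).

Retention rules, applied in order and idempotent:

1. **e-value** — strict `evalue < 1e-5` (configurable).
2. **Bidirectional reciprocity** — "reciprocal best" is ambiguous for a
   protein-versus-domain-model search, so it is implemented as mutual best
   *within a genome*: a hit survives iff it is its query's top-ranked model
   and its query carries the top bitscore among that genome's queries
   hitting the same model. This is the closest testable reading; it can be
   switched off (`require_bidirectional=False`). Note that with a
   single-model family, mutual-best collapses within-genome copy number;
   real domain databases provide multiple related models per family, and
   the synthetic hit generator mirrors that so planted copy numbers survive
   filtering.
3. **Specificity** — specific hits are kept; queries whose only surviving
   hits are superfamily-level are retained but tagged, and tallied in
   separate `<family>_superfamily` columns of the inventory (transporters
   assignable only at the superfamily level are a real and reportable
   category, not noise).

Counting unit: one count per protein per family by default (a multi-domain
protein hitting two models of one family counts once); `per_domain=True`
counts every hit. The inventory is a genome × family integer matrix over
*declared* genome and family universes, so absent combinations are explicit
zeros; a presence/absence view is derived as `counts > 0`.

## Motif scanning

Two modes, both exhaustive and deterministic (a deliberate replacement of
heuristic alignment search, which at 15–19 bp has no sensitivity advantage):

- **Reference scan** — every window on both strands is compared to every
  reference motif by Hamming distance; windows within `max_mismatches` of
  any reference are reported once with the minimum mismatch count.
  Non-ACGT bases always count as mismatches. Defaults: 3 mismatches for
  19-bp motifs, 2 for 15-bp; no tolerance is claimed faithful to any prior
  search, and both are config.
- **Inverted-repeat scan** — a window of `2·arm + spacer` bp qualifies when
  at least `min_palindromic_pairs` of the arm positions are
  reverse-complement pairs (position *i* against position *L−1−i*). The
  7-1-7 Fur-box geometry is the default (arm 7, spacer 1, all 7 pairs).
  Pairing is strand-symmetric, so hits are reported once, on the forward
  strand.

Coordinates are 0-based half-open. Upstream records are fixed 300-bp
windows in gene orientation (one per gene, FASTA id = gene id); 300 bp is a
typical bacterial promoter span and is configurable. Hit→gene assignment
takes the nearest downstream gene start on the matching strand within
`window_bp` (default 300); hits further away are left unassigned.
Overlapping qualifying windows are reported individually, never merged.

## Neighborhoods, enrichment, and locus classification

A neighborhood is the ±`window_genes` (default 10) genes around a focal
gene in gene-index order, truncated at contig ends. For enrichment, the
neighborhoods of a focal set are unioned before counting so a gene inside
two overlapping windows counts once. The universe is all genes of all
supplied genomes (pooled; a per-genome universe is available). For each
(focal set, family) the 2×2 table {inside/outside × family/other} is tested
with the one-sided (enrichment) hypergeometric upper tail — identical to
one-sided Fisher — and Benjamini–Hochberg correction is applied jointly
across all pairs in a run. Genes with several family labels contribute to
each family.

Locus classification is a pure function applying first-match-wins rules to
the family labels present in a neighborhood (plus, optionally, upstream
motif evidence). Default order: biosynthesis cluster (NRPS enterobactin
synthase subunits E/F) > heme (`hutB` **and** `hmuS`) > catecholate
(`fatB`) > hydroxamate (`fhuD`) > unknown siderophore (siderophore-
interacting protein only) > ambiguous fallback. The order encodes rule
specificity — biosynthesis evidence outranks uptake-only evidence — and is
fully overridable.

## Markov clustering

MCL is implemented from scratch on dense matrices (the intended problem
size is 10²–10³ sequences). The similarity graph must be undirected with
positive finite weights; nodes are ordered canonically (sorted ids) so
results are independent of input order. Self-loops are set to each node's
maximum incident edge weight (standard damping; a constant is available).
The column-normalized matrix is iterated with expansion (matrix power,
default 2), inflation (elementwise power, default 2.0, the canonical
choice), pruning of entries below 1e-5, and renormalization, until the
maximum absolute change falls below 1e-8 or 200 iterations (then a warning,
and clusters are read from the final iterate). Attractors are nodes with
positive converged diagonal; attractor systems are merged through residual
attractor–attractor flow; every node joins the system it flows to, with
overlaps resolved to the larger system (tie: lexicographically smallest
member). Clusters are labeled `MCL1, MCL2, …` by descending size;
singletons are labeled `MCLnull`. No monotonicity in inflation is asserted
— MCL has no such theorem — only component refinement (clusters never span
disconnected components) is guaranteed and tested.

## consenTRAIT trait depth

For a binary trait on a rooted tree with branch lengths, a clade qualifies
when ≥ 90 % of its tips are positive (`positive_fraction`, the algorithm's
conventional threshold; configurable). Maximal qualifying clades — those
without a qualifying ancestor — each contribute their mean branch-length
distance to their tips; positive tips outside every qualifying clade
contribute singletons at 0.5 × their terminal branch length
(`singleton_depth_factor`). τ_D is the mean of all contributions, so
τ_D(all-positive trait) equals the mean root-to-tip depth, and τ_D scales
linearly with branch lengths.

Uncertainty is aggregated across a supplied tree *set* (intended:
bootstrap replicates sharing the tip set): the reported mean/SD are across
trees, and a single tree yields SD 0. Significance comes from permuting the
tip→trait assignment (default 1000 permutations) and comparing the observed
mean τ_D with the permuted distribution, using the add-one (Phipson–Smyth)
estimator so p ≥ 1/(B+1). Traits significant at α = 0.1 are flagged, with
α = 0.05 for the D statistic, in the combined signal table.

## Fritz & Purvis' D

The observed statistic Σd sums, over internal nodes, the absolute
deviations of child values from their mean, where node values are computed
tips-to-root as unweighted means of child values (|v₁ − v₂| at
bifurcations; the deviation form handles polytomies). D rescales Σd_obs
between two simulated nulls on the same tree:

D = (Σd_obs − mean Σd_Brownian) / (mean Σd_random − mean Σd_Brownian)

with 1000 draws each by default. The random null permutes tip labels; the
Brownian null simulates Brownian motion (root 0, increments Normal(0,
branch length)) and thresholds at the empirical quantile matching the
observed prevalence exactly, ties broken by tip label order. p_random is
the fraction of random-null draws ≤ Σd_obs (small = more clumped than
random); p_brownian likewise. D is undefined (error) for constant traits
or when the two null means coincide.

Both statistics are evaluated through an array-flattened tree
representation so thousands of permutation/simulation columns are processed
in single vectorized passes; this is what keeps the 200-replicate,
1000-draw calibration runs in seconds.

## Lineage comparisons from summary statistics

Trait depths reported per lineage as mean/SD over bootstrap trees are
compared with Cohen's d = |m₁ − m₂| / √((s₁² + s₂²)/2), classified small
(< 0.5), medium, or large (> 1), and with Welch's unequal-variance t test
(Welch–Satterthwaite df) — the pooled-variance alternative is not
implemented because equal dispersion across lineages is exactly what the
data contradict. A published per-lineage summary table ships as package
data; running the comparison reproduces its effect-size annotations (six
shared categories, four deeper in SAR11; corA and znuA large, the Fbp-like
1 family small).

## Ordination layer

- **Bray–Curtis** on non-negative counts (all-zero rows are an error).
- **PCA** by SVD of the centered (optionally unit-variance-scaled; default
  center-only) matrix. Sign convention: each loading vector's
  largest-magnitude entry is positive. Eigenvalues are per-axis variances.
  PCA on the count matrix is the primary ordination; a principal-coordinate
  embedding of Bray–Curtis is provided for analyses that want distance
  space instead.
- **envfit** — continuous variables are regressed on the first 2 axes
  (configurable k); R² = 1 − SSres/SStot; the direction is the unit
  coefficient vector. Factors use R² = 1 − SSwithin/SStot of the scores
  around level centroids. p by permutation of the variable (default 999,
  add-one estimator).
- **Dispersion test** — each sample's distance to its group centroid in
  ordination space (PCA scores by default), a one-way F on those distances,
  and a permutation p from relabeling samples and recomputing centroids.
  This is a declared design (a permutation homogeneity-of-dispersion test);
  it is not claimed to replicate any particular published variant.
- **Spearman screens** use average ranks for ties, two-sided p, BH q across
  the requested pairs; constant variables are flagged and excluded from the
  BH pool. Chi-squared is Pearson's without continuity correction (flag
  available). BH is the standard step-up procedure.

## Synthetic data: what it emulates, what it does not

The generators produce inputs whose *statistical structure* matches what
the analyses assume, with ground truth recorded for testing:

- **Trees** — pure-birth (Yule) trees, ultrametric, tips `t1..tN`, birth
  rate set so the expected root-to-tip depth equals `scale` (default 1).
  Sufficient for calibration tests; no death, no rate variation.
- **Traits** — random (iid Bernoulli), clumped (smallest clade holding the
  target count seeded at an anchor tip, trimmed by patristic distance from
  the anchor, label-order tie-break), and Brownian-threshold (exact
  positive count via empirical quantile, label-order ties). Defaults:
  prevalence 0.25 for clumped/random contrasts, 0.5 for D calibration —
  the prevalence regimes the corresponding statistics are evaluated at.
- **Genomes** — one contig per genome, uniformly spaced genes (900 bp gene,
  100 bp gap), random strands, family labels drawn from a weighted pool;
  locus templates (e.g. TBDT+hutB+hmuS) planted as contiguous same-strand
  runs with a per-genome probability; 300-bp uniform-random upstream
  windows with the motif written verbatim (plus a stated number of random
  mismatches) at a stated offset for the first gene of each planted locus.
  No sequence evolution, codon structure, or indels — motif recall on this
  background measures scanning correctness, not discrimination against
  biological decoys.
- **Similarity graphs** — planted partitions: within-cluster edge
  probability `p_in` (mean weight `weight_in`, ~15 % spread), between
  `p_out` < `p_in`. Cluster recovery here shows algorithmic correctness;
  real bitscore graphs are weighted by homology, not block structure.
- **Count matrices** — two groups (default 42 + 22 rows, 25 features,
  mirroring the two-lineage genome survey shape) sharing feature means with
  group-specific additive noise SD (default 5 : 1, the dispersed
  patch-adapted group first) and one covariate linearly related (plus unit
  noise) to row totals, emulating genome features that track transporter
  counts. Integer-clipped Gaussians, not count-generating processes; the
  dispersion test consumes distances, so the marginal family is not
  critical.

All generators are deterministic per seed; every pipeline output is
byte-identical under a fixed config and seed.

## Problem sizes and tolerances

Calibration and null-uniformity checks use 64-tip trees, 200 replicates and
1000-draw nulls for D (tolerance ±0.15 around 0 and 1), 500 simulations ×
200 permutations for p-uniformity (KS p > 0.01), 20 seeds for 20+20-node
planted-partition recovery (ARI ≥ 0.9), and exhaustive 2×2 enumeration to
N = 60 for the Fisher tail (machine precision, < 1e-12). These sizes give
Monte-Carlo standard errors comfortably inside the stated tolerances while
keeping the full suite and the acceptance script at about a minute each.

## Known limitations

- The bidirectional-reciprocity reading (mutual best within genome) is one
  defensible interpretation of reciprocal filtering against domain models;
  alternatives would change borderline retentions.
- The motif scanner has no positional weighting or energy model; mismatch
  counts treat all positions equally.
- The dispersion test permutes labels over centroid distances recomputed
  per permutation; with strongly unbalanced groups its null can be mildly
  liberal, which the uniformity check bounds empirically at the tested
  sizes.
- MCL cluster *numbering* is size-ranked and not comparable across runs
  with different inputs; only memberships are meaningful.
- The pipeline's CLI is a thin orchestration layer; concurrency is limited
  to nothing fancier than vectorized permutation batches.
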