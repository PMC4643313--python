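# Methods

This note documents the models implemented in `lineagetx`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Expression quantification

**Size factors.** The median-of-ratios estimator: for each gene expressed
in every sample, the ratio of its count to its across-sample geometric
mean; the per-sample size factor is the median of those ratios. Genes with
any zero count are excluded from the reference because their geometric
mean vanishes. The estimator is defined only up to a constant, so factors
are rescaled to geometric mean 1; the synthetic generator centers its
planted log library-size factors the same way, making the two directly
comparable.

**FPKM.** The plain formula `count / (kb of exon × millions of mapped
fragments)`. The per-sample fragment total defaults to the column sum of
the analyzed matrix; an external total can be supplied. No effective-length
or amplification-bias modeling is attempted.

**Variance-stabilizing transform.** For NB counts with variance
`μ + αμ²` (dispersion `α` shared across genes), the stabilizing transform
is the antiderivative of `(μ + αμ²)^{-1/2}`:

    vst(x) = (2/√α) · asinh(√(α·x)),   vst(x) → 2√x as α → 0.

Applied to size-factor-normalized counts. When `α` is not supplied it is
estimated by pooled method of moments — the median over genes of
`(s² − x̄)/x̄²` on normalized counts — floored at 1e-8. The closed form
agrees with numerical quadrature of the integral to better than 1e-6 over
a wide (α, x) grid (acceptance report: ~1e-13), and on NB simulations with
common dispersion the variance of VST values is flat within a factor of 2
over a 100-fold mean range.

**Mean-relative (stage-scaled) expression.** Replicates are averaged
within stage first; each gene's `log₂(stage mean + 1)` profile is centered
on its cross-stage mean. Pseudocount 1 and log base 2 are used for all
log-normalized quantities (both configurable); rows sum to zero by
construction, which is what makes "positive = preferentially active"
meaningful for the network overlay.

## Differential expression

The test is the exact conditional NB test on replicate groups. For one
gene and contrast (A, B): the pooled per-size-factor mean is
`q = (K_A + K_B)/Σs_j`; each group sum is modelled as NB with mean `q·Σs`
and variance `Σ_j (q s_j + α q² s_j²)`. Conditional on the observed total,
the two-sided p-value is the total probability of splits at most as
probable as the observed one (ties included with relative slack 1e-8).
Splits are enumerated exactly over `0..K_A+K_B`; the implementation matches
a brute-force enumeration oracle to <1e-10 for all totals ≤ 40 and is
invariant to sample order. Log₂ fold changes use size-factor-normalized
group means with pseudocount 1.

**Dispersion.** Per gene: within-condition method-of-moments estimates
pooled across conditions with ≥2 replicates, then regularized as the
maximum of the gene-wise estimate and a fitted `a₀ + a₁/mean` trend
(non-negative least squares), floored at 1e-8. The maximum is deliberately
conservative; on Poisson simulations the median estimate is <0.01 and a
planted α = 0.2 is recovered within [0.1, 0.4] at 8 replicates. Null
calibration of the test itself (2,000 flat genes, α = 0.1, 4 vs 4) gives a
raw p < 0.05 fraction of ≈0.045–0.05.

**Multiple testing.** Benjamini–Hochberg step-up (via statsmodels).
Pipeline gating defaults to adjusted p < 0.05; raw p-values are always
emitted alongside, since published significance thresholds do not always
state the adjustment.

## Dynamic genes and expression modules

A gene is **dynamic** when (i) significant in at least one pairwise stage
contrast at adjusted p < 0.05 ("differential between at least two stages";
a `min_contrasts` knob tightens this) and (ii) robustly detected —
stage-mean FPKM > 10 in at least one stage. Both thresholds are exposed
and logged.

Modules are found by agglomerative clustering of the mean-relative
profiles of dynamic genes: distance 1 − Pearson correlation (shape-based;
constant rows get distance 0 to each other and 2 to varying rows), average
linkage, tree cut into exactly k clusters (default k = 10; a height cut is
available). Labels are renumbered 1..k in dendrogram leaf order, making
the assignment deterministic and order-stable. Because stray
false-positive genes can otherwise consume cluster slots, the cut is
robust: if the plain k-cut produces clusters below `min_module_size`
(default 5), the tree is over-cut to the smallest k′ ≥ k yielding k
adequately sized clusters, the k largest are kept, and remaining genes are
assigned to the nearest module centroid by correlation. For tiny inputs
where no such k′ exists the plain cut is used, preserving boundary
behaviour (k = n gives singletons). Under the planted conditions
(2,000 genes, 200 dynamic in 10 modules with 4-fold effects, α = 0.1,
4 replicates/stage) selection recall is ≥0.95, false-selection ≤0.1 and
the adjusted Rand index against the planted modules is ≥0.95.

## Diffusion-map staging

Gaussian kernel `exp(−d²/2σ²)` on Euclidean distances between sample
profiles (VST of dynamic genes by default); density normalization with
anisotropy exponent 1 (divide by the product of row and column kernel
sums); row normalization to a stochastic operator; eigendecomposition via
the symmetric conjugate for stability. DCs are eigenvectors 2..m+1 ordered
by eigenvalue. Bandwidth `auto` is the median nonzero pairwise distance.
Components are defined up to sign; when a stage order is supplied each DC
is oriented to correlate non-negatively with it, otherwise the first
nonzero loading is made positive. No locally adaptive bandwidth and no
pseudotime beyond the DC coordinates.

## Network activity

The reduction takes the induced subgraph of a directed signed network on
(dynamic genes ∪ anchors); anchor regulators (default Pou5f1, Nanog, Sox2)
are retained even when isolated, other isolated nodes are dropped unless
requested. Symbol matching is case-insensitive with an optional synonym
map, since curated networks and expression tables often differ in casing.
Activity is strict: a node is active at a stage iff its mean-relative
expression is strictly positive there (a flat gene is active nowhere); an
edge is active iff both endpoints are. The connectivity profile reports
per-stage active node/edge counts and flags the stage of maximal edge
count (first stage on ties). On planted networks whose node profiles all
peak at one stage, that stage is recovered in ≥95% of simulations
(acceptance report: 100/100).

## Pathway scores and enrichment

A pathway score per condition is the summed member FPKM divided by pathway
size. Members absent from the matrix are excluded from the size by default
(`count_missing=True` divides by the full set size instead) — the
"pathway size" convention is ambiguous in common usage, so both are
offered. Scaled scores divide each pathway row by its cross-condition
mean (rows then average 1; all-zero rows stay 0 and are flagged).
Enrichment is the hypergeometric upper tail `P(X ≥ k)` over a user-supplied
universe with BH correction across the collection; no ontology-aware
conditioning is attempted since topology is not shipped.

## Immunofluorescence quantification

Marker channels are divided by the same cell's DAPI intensity (cells with
missing/zero DAPI are dropped and counted), which removes per-cell scale
effects. Positivity defaults to Otsu's threshold on the log₁₀ normalized
intensities per embryo (log-normal intensity modes are symmetric in log
space); embryos with <3 cells fall back to the global threshold; fixed and
quantile rules are available and every applied threshold is logged.
Classes are NANOG-only (N+/G−), GATA6-only (G+/N−), coexpressing (N+/G+)
and double-negative — mutually exclusive and exhaustive by construction.

**NANOG-high.** A NANOG-positive cell whose normalized NANOG intensity is
at least 1.5× (inclusive) a reference average. The reference is the mean
over the *NANOG-positive* cells of the same embryo by default
(`high_ref="positive"`): with realistically dim negative cells, an all-cell
average sits far below the positive population, so 1.5× of it would flag
the bulk of positive cells and the statistic would no longer discriminate
a bright subpopulation — under that reading, uniformly upregulating NANOG
*lowers* the flagged fraction because the reference rises faster than the
tail. The all-cell reference (`high_ref="all"`) and a per-treatment scope
remain available.

**Statistics.** One-way fixed-effects ANOVA on per-embryo statistics (the
embryo is the experimental unit; per-cell testing would pseudo-replicate)
with Tukey HSD pairwise p-values from the studentized-range distribution
(Tukey–Kramer standard errors for unequal group sizes). With two groups
the Tukey p equals the pooled two-sided t-test (q = |t|·√2), verified
numerically; for k = 3 the p-values match direct numerical integration of
the studentized-range distribution to 1e-4. Degenerate inputs: identical
groups give F = 0, p = 1; zero within-group variance with unequal means is
floored at p = 1e-15. Null calibration over 1,000 replicates of 3×6
designs: overall type-I ≈ 0.05, Tukey family-wise error ≤ 0.07.

## Synthetic-data generator

The generator emulates the statistical structure of a lineage-resolved
embryo RNA-seq study, not its biology:

- **Counts**: NB with mean `baseline × module profile × library factor`
  and variance `μ + αμ²` (Poisson at α = 0); per-gene baselines are
  log-normal around `baseline_mean` (log-sd 0.5, mean-preserving).
  Defaults: 2,000 genes, 4 ordered embryonic stages (E2.5, E3.5, E4.5-EPI,
  E5.5; any ordered label set is accepted, `FULL_STAGES` adds E4.5-PrE,
  ESC and diapause), 4 replicates per stage, baseline mean 50, α = 0.1,
  library-size log-sd 0.2.
- **Dynamic structure**: 10% of genes are dynamic, assigned cyclically to
  10 modules. Two profile families are provided:
  `default_module_profiles` (distinct stage-subset blocks at 4-fold
  amplitude — maximally separable shapes for module-recovery studies) and
  `smooth_module_profiles` (Gaussian bumps of width 1.5 stages along the
  stage axis — autocorrelated stage geometry for staging studies, since
  sample ordering is only identifiable when adjacent stages share
  activity).
- **Detection**: 65% of genes are expressed (`frac_expressed`), matching
  the 60–70% detection rates characteristic of small-cell-number RNA-seq;
  unexpressed genes are never dynamic.
- **Networks**: nodes drawn from dynamic genes whose profile exceeds its
  cross-stage mean at the recorded peak stage; `round(density·n·(n−1))`
  directed edges sampled without replacement with random signs.
- **IF tables**: per-cell log-normal intensities (DAPI mean 1000, positive
  markers 600, negative 60, log-sd 0.30–0.35) with lineage classes drawn
  from a control mix (25% NANOG-only, 35% GATA6-only, 10% coexpressing,
  30% double-negative) and independent 30% CDX2 positivity. Treatment
  effects multiply class probabilities, scale channel means, and/or boost
  the NANOG intensity of a fraction of NANOG-positive cells (the
  "NANOG-high" phenotype).
- **Determinism**: all draws come from one seeded generator; identical
  configurations give identical outputs. Ground truth (flags, module
  labels, true stage means, library factors, pseudotime, peak stage, cell
  classes) is returned and serializable, so every downstream recovery test
  closes without external input.

What it does **not** emulate: read-level artifacts (no FASTQ, no 3′ bias,
no GC effects), gene–gene correlation beyond shared module profiles,
batch effects, cell segmentation errors or spatial structure in images.
Passing recovery tests therefore demonstrate correctness of the
algorithms under the stated statistical model, not robustness to every
real-data pathology.

## Numerical conventions and problem sizes

- NB pmf via scipy with `size = 1/α`; group-sum variances below the mean
  fall back to Poisson.
- p-value tie comparisons use relative slack 1e-8; dispersion floor 1e-8;
  ANOVA p floor 1e-15.
- Agglomeration ties are resolved by scipy's deterministic linkage order;
  module labels are canonicalized by leaf order.
- Default problem sizes in the test and acceptance runs — 2,000 genes ×
  16 samples for recovery studies, 100 simulated networks of 300 genes,
  1,000 ANOVA null replicates, 1,440 cells for the IF experiment — keep a
  full run within about half a minute on one CPU while leaving comfortable
  statistical margins.

## Known limitations

- The exact test enumerates all splits of a gene's total; for totals in
  the millions a normal-approximation test would be preferable (not
  implemented — the intended regime is small-cell-number libraries).
- Single-factor designs only: no covariates, no fold-change shrinkage.
- The VST uses one common dispersion; strongly gene-specific dispersion
  profiles will stabilize imperfectly.
- Otsu thresholds assume a bimodal intensity distribution per embryo;
  markers with graded expression need the fixed or quantile rules.
- Gene identifiers are opaque strings; no ortholog or synonym database is
  shipped beyond the optional user-supplied map.
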