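# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the conditions used by the
validation experiments. It records design rationale only; every
empirical number it mentions is computed by the test suite or by
`scripts/acceptance.py`.

## Encephalization index

Ei is the residual of an OLS regression of log brain mass on log body
mass, fitted on the analysis species. Base-10 logarithms are the default
(allometric convention); the base only rescales residuals by a positive
constant, so downstream Pearson correlations are unaffected. Residuals
from a larger reference regression can be attached instead
(`attach_external_ei`), in which case provenance is recorded and the
internal fit is bypassed. Masses must be strictly positive; fewer than
three species is an error.

## Per-family screen and permutation null

For each family, Pearson r and a two-sided t-distribution p-value are
computed against Ei and against MLSP. Zero-variance families carry an
undefined r: they are flagged, excluded from tail counts and from every
selection stage. The positive/negative tail imbalance is tested with a
2-cell goodness-of-fit χ² (1 df) and with a Monte-Carlo null. Two
permutation modes exist:

* `per_family` (default): each family's counts are permuted across
  species independently per replicate — matches the description of the
  procedure being emulated;
* `shared_relabel`: one species permutation per replicate, preserving
  cross-family covariance — statistically safer when families are
  correlated; the mode used is recorded in the result.

Empirical p-values always use the +1 correction, so they are never 0 and
are valid at finite sample sizes. Partial correlations use the
first-order identity r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))
with a t test on n−3 df, which equals the multiple-regression t test on
the Ei coefficient; a collinear covariate (|r| = 1 between Ei and MLSP)
is an error. The selection cascade uses α = 0.05 with the joint
condition r > 0 AND two-sided p < α at each stage; α is configurable and
logged.

## Pagel's λ under PGLS

The model is y ~ N(Xβ, σ²C(λ)) with C(λ) the Pagel transform of the
tree's shared-path matrix: off-diagonal entries scaled by λ ∈ [0, 1],
diagonal (root-to-tip depths) untouched, so non-ultrametric trees and
polytomies are handled. Estimation is maximum likelihood (not REML): a
20-point grid scan locates the basin, bounded Brent refines to 1e−6, and
the reported optimum is never worse than the grid or the boundaries.
LRTs against λ = 0 and λ = 1 use χ²(1) without a boundary mixture
correction, which makes the λ = 0 test conservative; a boundary optimum
gives LR = 0 and p = 1 by construction. Near-singular covariances
receive one jitter of 1e−10 × mean(diag); star phylogenies (all shared
paths zero) make λ unidentifiable and are flagged degenerate with
λ̂ = 0. σ² is floored at 1e−12 so perfect fits yield finite
log-likelihoods.

When fitting family count matrices (`fit_lambda_matrix`) the response is
log(1+GFS) by default. Raw Poisson counts under a log-linear mean are
heavy-tailed: a single copy-rich species can dominate the Gaussian
likelihood and spuriously favor λ = 1 through the determinant term,
which we observed directly on planted Ei-linked (phylogeny-free)
families. The log scale is also the conventional one for size traits.
`log_counts=False` restores raw-count fitting.

The elimination rule marks a family as phylogenetically confounded iff
p(λ=0) < 0.05 AND p(λ=1) > 0.05 — signal significantly above zero and
indistinguishable from full Brownian structure — and such families leave
the cascade.

## GO tests

Terms map to families by the any-member rule (a term annotating any
member gene annotates the family; duplicates collapse by set semantics)
and are eligible when they cover strictly more than 50 families. The
mean-correlation test compares a term's average family r with means of
equally sized random family samples; implementation-wise, each replicate
draws one family permutation and every term of size k reads its null
mean from the first k entries (prefix sums), which reproduces each
term's exact marginal null at a fraction of the cost. A 1e−12 tie
tolerance absorbs last-ulp differences between prefix sums and direct
means.

The enrichment test counts |term ∩ S| for a selected family set S and
divides by the annotation density d(S) = (annotation events of S over
eligible terms)/|S|; the null recomputes the statistic on random subsets
of the background of size |S|. Annotation events are counted over
eligible terms only — the bias being corrected lives inside the tested
term universe. Dividing observed and null counts by their own sample's
density makes the statistic invariant to a global doubling of
annotations and keeps the test calibrated when the selected set is
simply annotated more densely overall; the raw-count variant
(`adjust=False`) exists to demonstrate that failure mode. Bonferroni
m = number of eligible terms in the run. Only the greater tail is
tested for enrichment.

## Expression

Prominence operates on a one-value-per-tissue panel (means over samples
per tissue): brain rank = 1 + number of tissues strictly above brain;
prominent iff rank ≤ 2. Ties share the brain's rank, a conservative
rule. Family-level enrichment resamples families (genes inherited) —
never genes — because the selection being tested is family-structured.
Developmental-variance genes are the top percentile (default 10) of the
ratio Var(cortical expression | age ≤ 18 yr)/Var(| age > 18 yr); both
thresholds are parameters, and an externally supplied gene list can be
used instead. Genes constant in both periods are excluded as degenerate.
Regional categorization takes the argmax of mean expression over CX, SC,
CB with fixed tie priority CX > SC > CB. Expression values are used as
given; no re-normalization is applied.

Sample blocks are named by an optional `panel` metadata column
(tissue | regional | developmental) written by the generator; when
absent, region labels are the fallback. This prevents the developmental
cortical series from contaminating the adult regional comparison.

## Co-expression network

Unsigned adjacency |cor|^β over the developmental cortical samples. β is
the smallest power whose connectivity histogram fits a power law with
signed R² ≥ 0.8 (R² × −sign(slope): an increasing degree distribution
never qualifies); when binned connectivity spans less than 2×, the fit
is reported as 0 rather than a spurious R², and if no power reaches the
target the argmax is used with a warning. TOM follows
(Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij); modules come from
average-linkage clustering of 1−TOM with a static cut at 0.99 of the
maximum merge height, clusters below 30 genes falling back to module 0.
Static cut rather than dynamic tree cut keeps the procedure fully
reproducible and parameterized. Eigengenes are first-PC sample scores of
the z-scored member submatrix, unit norm, sign-oriented to correlate
non-negatively with members on average. Hubs maximize intramodular
connectivity, ties lexicographic. No eigengene-based module merging is
performed.

## Synthetic-data generator

What it emulates, and what it does not: the generator reproduces the
*statistical structure* the analysis assumes — allometry with iid
residuals, a lifespan confounder with tunable correlation to Ei
(affine-transformed mixture, floored at 1 yr, so the realized Pearson
correlation converges to the target), Poisson family counts with
log-linear planted effects, annotation-density bias, planted expression
signatures — but none of the biology of gene birth/death along
lineages, no sequences, no gene trees. Passing tests therefore
demonstrate that the procedures are correct and calibrated under their
own assumptions, not that real Ensembl/AnAge/BrainSpan data satisfy
those assumptions.

Key defaults: allometric slope 0.75, intercept −1.3 log10 g, Ei sd 0.25
log10 g (typical mammalian residual spread), body masses Brownian on the
tree around 10^3.5 g with sd 1.5 log10 units, MLSP 30 ± 10 yr, Poisson
base_log_mean 1.0 (≈ e ≈ 2.7 copies per species), planted effect size
1.0 on standardized Ei/MLSP. Counts are Poisson around
exp(base + βx + φ) — not birth–death gain/loss — because this gives
direct control of effect sizes and truth labels; phylogeny-only families
receive a unit-variance Brownian deviate φ. Families failing the
presence rule (count > 0 in ≥ 6 species) are redrawn up to 20 times,
then dropped and recorded. Trees are pure-birth with terminal branches
extended by the waiting time to the next speciation event; stopping
exactly at the n-th split would leave zero-length sister branches and
make sister species artificially identical.

Module expression uses orthogonalized smooth latent curves (QR over
random sine/polynomial curves), member loadings set so pairwise member
correlation equals `module_corr`, and one hub per module with a 1/0.6
loading ratio. Planted prominent and developmental genes can be coupled
to a target gene set at a configurable odds fold, which is how the
bundled demo couples expression signatures to Ei-linked families.

## Validation-experiment conditions

All experiments run on one core in seconds to a couple of minutes; sizes
were chosen accordingly and are recorded here as the package's own
choices.

* Null calibration: 30 clades × 2000 families × 40 species, 1000
  permutations each.
* Planted recovery and confounder removal: 10 clades × 1000 families ×
  40 species; 20% Ei-linked (plus 20% MLSP-linked in the confounder
  experiment, MLSP–Ei target correlation 0.79), effect size 1.0.
* λ recovery: 64-tip tree, 100 Brownian and 100 iid replicates.
* Phylogenetic filter discrimination: 10 clades × 160 families, 30%
  Ei-linked / 30% phylogeny-only, base_log_mean 5 (≈ 150 copies per
  species) so sampling noise does not mask the heritable signal, and the
  generator's true Ei as predictor so the experiment measures the
  filter, not upstream Ei-estimation error. At the default base of 1.0
  the Brownian signal of a planted family is genuinely dominated by
  Poisson noise and its true λ (in the signal-fraction sense) is far
  below 1, so low elimination there reflects the data, not the filter.
* GO density adjustment: 5 runs × 100 terms × 1500 families, density
  bias 2×, 10,000 resamples.
* Prominence null: 20,000 genes × 16 exchangeable tissues.
* Module recovery: 20 runs, 5 modules × 50 genes, module correlation
  0.8, 60 developmental timepoints (BrainSpan-like sampling density).

## Known limitations

* The λ = 0 LRT is conservative (no boundary mixture); the λ = 1 test is
  sharply powered against even small iid noise when the tree contains
  short sister branches — an inherent property of the rule, visible in
  the filter experiment.
* Pearson p-values rely on the t reference, adequate at ~40 species for
  Poisson counts but approximate for very small clades.
* The adjusted GO statistic corrects a *global* density bias; a bias
  concentrated in a few terms is indistinguishable from true enrichment.
* Module count and β are data-dependent; on strongly modular synthetic
  data the scale-free target is often unreachable and the argmax
  fallback (with warning) is the normal path.
* Absolute Ei values from the original 493-species reference regression
  are not reproducible here; only the procedure is, plus the external-Ei
  path for users who have such a table.
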