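# Methods

`microsig` implements a two-branch discriminative analysis for two-group
(case-control) gut-microbiome cohorts, plus the synthetic cohorts used to
validate it. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## Data model and transform

Input is a samples × taxa matrix of relative abundance in **percent**
(0–100) at one taxonomic rank, with a binary group label per sample
(0 = non-metastatic, 1 = metastatic). Abundances stay on the percent
scale everywhere outside the transforms, matching how such tables are
published.

The modeling scale is the **logit Z-score**:

1. *Zero replacement.* Every exact 0% is replaced by half of the smallest
   nonzero percent in the entire matrix. This is a detection-limit
   convention: half of the smallest observed value stands in for "present
   below detection".
2. *Logit.* p = percent/100, x = ln(p/(1−p)). Strictly monotone, so
   rank-based statistics are unaffected; it removes the (0, 100) range
   constraint.
3. *Standardization.* Each taxon column is centered and scaled to sample
   SD 1 (denominator n−1) over the **pooled cohort** — both groups
   together, never per group. Pooling is what makes the group means of a
   Z column roughly mirror images around 0 and underlies the
   absent-member arithmetic below.

Zero-variance columns (e.g. a taxon absent everywhere) cannot be
standardized; they are dropped from the Z matrix and recorded with their
constant logit value.

A feature that is constant (all zeros) within *one* group still has a
well-defined Z column: within that group it is the constant c implied by
the pooled zero-mean constraint n₀·c + n₁·m̄₁ = 0, where m̄₁ is the other
group's mean Z. `absent_group_constant` exposes this identity; the
centroid operation can impute such members from per-group constants,
which reproduces published per-cluster tables that report "Absent" for
one group.

**Cluster centroid.** The centroid of a taxon set is the per-sample
unweighted mean of member Z columns. Group means of a centroid are
therefore the plain average of member group means (linearity); this is
asserted to 1e−12 in tests and is how the published centroid values are
checked. Centroid group comparisons use Welch's two-sample t-test,
switching to the Mann–Whitney U test when either group has zero variance
(the t statistic is degenerate there); the switch can be overridden.

One published species-level cluster (cluster 1) has printed centroid
group means (−0.181/0.162) that do *not* equal the average of its printed
member means (−0.200/0.179), unlike the other four clusters, which
reproduce exactly. The discrepancy is unexplained at the source; the
package implements the linearity rule and validates against the four
reproducible clusters only.

## Branch 1 — PELORA supervised clustering

PELORA grows groups of taxa whose **averaged** Z-score separates the two
groups, by greedy forward selection under the L2-penalized negative
Bernoulli log-likelihood

J(β) = −Σᵢ [yᵢ ln πᵢ + (1−yᵢ) ln(1−πᵢ)] + λ Σ_{j≥1} βⱼ², π = logistic(Xβ),

where X carries an intercept (unpenalized) and one column per cluster
centroid. At each step every unused taxon is evaluated by recomputing the
growing cluster's centroid with it included and refitting the logistic
model; the largest criterion decrease wins, and growth stops when no
candidate improves J by more than `tol` (1e−6). A finished cluster is
frozen — its membership never changes — but its centroid stays in the
design while later clusters grow, so cluster 2 is built *conditionally*
on cluster 1. At most two clusters are kept by default, for
interpretability.

The inner ridge-logistic fit is damped Newton/IRLS, converged to gradient
norm < 1e−8 (hard error after 100 iterations); fitted probabilities are
clipped at 1e−12 inside the criterion. Tests verify the fit against a
numeric-gradient oracle, a scalar brute-force (profiled golden-section)
oracle, and unpenalized logistic regression at λ = 0.

Parameters:

* `lam` (λ ≥ 0): ridge penalty on centroid slopes; default 1/32, the
  default of the canonical R reference implementation of the algorithm.
* `max_clusters`: 2.
* `tol`: 1e−6 criterion decrease per addition.
* `sign_flip`: optional mode in which a candidate may enter a centroid
  negated. Off by default: published clusters contain members with
  opposite group directions yet their centroids match plain means, so the
  plain-mean convention is the one that reproduces the published
  arithmetic.

**Penalty tuning.** λ is chosen from a grid (default 13 log-spaced values
10⁻³…10³) by refitting on bootstrap resamples (default 50) and scoring
0/1 misclassification at threshold 0.5 on each resample's out-of-bag
samples; the λ with the lowest **median** rate wins, ties resolved toward
the larger λ (more regularization, stabler clusters). Resamples missing a
class are redrawn and logged. The same resamples are shared across the
grid, making the comparison paired.

Greedy growth equals exhaustive step-by-step forward search (proved by an
independent oracle on p ≤ 8 instances over 20 seeds); the criterion trace
is non-increasing by construction.

## Branch 2 — iterative Random Forest and interaction mining

The iRF loop: iteration 1 fits a random forest with uniform
split-candidate sampling; iteration k+1 draws each node's `mtry`
candidate features *without replacement with probability proportional to
the previous iteration's (non-negative, renormalized) Gini importances*.
K = 1 is therefore an ordinary random forest; an all-zero importance
vector resets the weights to uniform (logged). The trees are an in-house
CART (vectorized split search, class-1 leaf fractions as values) because
node-level weighted candidate sampling is not available in mainstream
tree libraries. Out-of-bag probability of a sample is the fraction of
trees not containing it that vote class 1; samples never out of bag get a
missing probability and are excluded from AUC with a warning.

Defaults: `n_trees` 500, `mtry` ⌈√p⌉, `max_depth` 10,
`n_iterations` K = 5; `tune_iterations` picks K from a grid (within
1…100) by OOB AUC, ties to the smallest K.

**Interaction mining.** For each of `n_boot` (default 30) outer bootstrap
perturbations, the K-iteration forest is refit; every leaf predicting
class 1 contributes the set of distinct features on its root-to-leaf path,
weighted by its sample count (class-1 leaves only: the interactions of
interest predict the positive outcome). Generalized Random Intersection
Trees (depth 5, branching 2, 500 trees by default) repeatedly intersect
randomly drawn itemsets; surviving sets of size ≥ 2 are that bootstrap's
recovered interactions. The **stability score** of an interaction is the
fraction of bootstraps recovering it (0 = never, 1 = always). Path-itemset
semantics (unsigned feature sets) are used; thresholded/signed binary
features would be a finer-grained alternative, but the path-set form is
the standard generalized-RIT formulation for forests.

**Quality metrics.** AUC uses the rank (Mann–Whitney) formulation with
ties counted ½; its 95% CI is the 2.5/97.5 percentile of AUC over 1000
stratified (within-class) bootstrap replicates. Variable importances are
summed Gini impurity decreases, reported also rescaled so the maximum is
exactly 100% (relative VIMP); non-positive values are flagged as
excluded-from-display.

## Interpretation

*ALE* (first-order): quantile bins (default 20; duplicate edges from
heavy ties — e.g. the replaced-zero value — are merged so all bins are
nonempty); a bin's local effect is the mean over its samples of
f(x with feature at upper edge) − f(x with feature at lower edge);
effects are accumulated and centered so the count-weighted mean is zero.
ALE = 0 therefore marks the average predicted risk.

*2-D PDP*: grids at marginal quantiles (default 20 × 20); a cell's value
is the mean prediction over all samples with the pair clamped to the
cell; cells ≥ 0.5 are flagged high-risk.

Selection is pure filtering: ALE for features with relative VIMP > 10%,
PDP for pairs with stability > 0.70, network edge lists at stability
≥ 0.5.

## Associations

All-pairs Spearman correlation between a taxa block and a metabolite
block: Pearson correlation of average ranks, two-sided p from the t
approximation on n−2 degrees of freedom, significance at raw p < 0.05 by
default (no multiplicity correction, matching the descriptive convention
of the source analysis; BH-FDR is available behind a flag). Because
Spearman is rank-based, raw percents, logits and Z-scores give identical
results — asserted as a property test.

## Synthetic cohorts

The generator draws, per taxon, a latent Gaussian on the log scale
(taxon-specific mean and SD), applies a softmax closure to percent
compositions summing to 100, then zeroes all entries below the
`zero_rate` quantile of the matrix (detection limit; realized zero
fraction ≈ `zero_rate`).

Design choices that matter:

* Taxon log-scale means ~ N(−4, 2) give a few dominant taxa and a long
  rare tail (heavy right-skew, as in real per-rank profiles).
* Dominant taxa get small log-scale spread (≈0.35 vs 0.8–1.6 for rare
  taxa). Real tables behave this way — a 40%-mean phylum varies far less
  on the log scale than a 0.01% taxon — and it keeps the softmax
  denominator stable, so a planted latent shift of δ arrives on the logit
  scale nearly intact.
* Planted-signal taxa sit at moderate baseline abundance (≈0.5–2%, like
  the members of published discriminating clusters): rare enough not to
  perturb the closure (an abundant planted taxon would leak an apparent
  opposite shift into every other column), abundant enough not to be
  truncated by the detection limit.
* Planted interactions drive the label through a logistic rule with main
  and product terms on standardized latent features; default coefficients
  (b_main = 1.5, b_inter = 5.0) are calibrated so the oracle rule's AUC
  on the observed logit features is ≈ 0.86 — discriminative power on the
  order of published species-level microbiome classifiers — making the
  pair learnable but far from deterministic.
* Metabolite–taxon associations use a Gaussian copula with Pearson
  loading r = 2 sin(πρ/6), which targets Spearman ρ exactly on normal
  margins; |ρ| > 0.99 is rejected as infeasible.

What the benchmarks show — and what they do not. Passing the recovery
suite shows the algorithms find planted structure of realistic effect
size under compositional closure, zero inflation and right-skew at the
study's sample sizes. The generator does **not** emulate phylogenetic
correlation between taxa, sequencing-depth variation, batch effects, or
taxon-taxon ecological dependence beyond the closure; recovery here does
not certify performance on real cohorts with those features.

## Problem sizes in validation

The validation suite runs the recovery studies at deliberately compact
sizes chosen as the smallest at which the planted effects are reliably
expressed: supervised-clustering recovery at n = 60, 45 taxa, 20 seeds;
interaction recovery and its permutation null at n = 200, 20 features,
20 seeds each, with 100-tree 2-iteration forests, 10 outer bootstraps and
250 intersection trees; forest sanity checks at 150 trees. Production
defaults (500 trees, 30 bootstraps, 500 RIT trees) are larger; stability
scores at the validation sizes are coarser (granularity 0.1) but the
pass/fail properties are insensitive to this, which is why those sizes
were chosen.

## Known limitations

* The greedy forward search is exact forward selection, not global subset
  search; it can be trapped by a single strong feature when λ is large.
* OOB probabilities from small forests are coarse (granularity
  1/#OOB-trees); AUC CIs at n ≈ 50 are wide, as in the source setting.
* RIT stability depends on `n_boot` granularity; with 10 bootstraps
  scores are multiples of 0.1.
* The pipeline treats ranks independently; no cross-rank coupling.
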