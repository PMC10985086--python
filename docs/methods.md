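# Methods

This note records the modelling assumptions, the numerical conventions, and
the design decisions behind riskcarver, in the order the pipeline runs.

## Synthetic cohort generator

The generator emulates a retrospective case-control study. It draws labels
first, at the exact configured case/control counts, and then draws features
from the class-conditional distributions implied by a logistic risk model:
a continuous feature with control distribution N(μ, σ²) and effect β
(log-odds per unit) has case distribution N(μ + βσ², σ²); a binary feature
with control probability p has case probability sigmoid(logit(p) + β);
ordinal features are exponentially tilted. The induced posterior is exactly
P(case | x) = sigmoid(β₀ + Σ βⱼxⱼ + risk shift), and for a single Gaussian
feature the population ROC-AUC has the closed form Φ(βσ/√2). We chose the
retrospective direction deliberately: it fixes the case/control counts the
way a matched design does, and it makes the closed-form AUC exact, which
the validation studies rely on. (Sampling features first and labels from a
Bernoulli draw would leave the counts random and, because the feature
marginal then stays N(0, 1) rather than the two-component mixture, would
depress the AUC below the closed form — by 0.03 at β = 1.19.)

**Archetypes.** A latent subgroup is a conjunctive threshold rule plus a
log-odds risk shift and a prevalence. Subjects are assigned to archetypes
retrospectively (Bayes at a background case probability calibrated by
bisection so the population case fraction matches the configured one, to
1% in at most 100 iterations); members' features are redrawn from the
class-conditional distributions truncated to the rule region. Ground truth
is then re-derived by applying the rules to the final features,
first-match in declaration order — so `true_archetype` is a deterministic
function of the data, and a background subject that happens to satisfy a
rule is a genuine member. `true_risk` is the exact posterior given the
features and archetype, up to ignoring the (rare) feature-archetype
dependence created by truncation.

**Dates.** Integer days from an arbitrary epoch; a year is 365 days.
Assessment dates are uniform over three years; the assessment-to-index gap
is uniform over the configured interval, half-open below and closed above
((0, 5·365] for discovery, (5·365, 11·365] for holdout). Missingness is
completely at random, per feature. Longitudinal biomarkers are monthly
values (30-day months) over the five years before the index date:
subject mean (between-subject SD, optional case shift) plus stationary
AR(1) noise; prescriptions are Bernoulli events per year bin with
class-specific probabilities. Control matching requires observational
coverage of, and no death during, the five years before the assigned index
date; ties among eligible controls break uniformly at random under the
seed.

What the generator does **not** emulate: informative missingness, feature
correlation beyond what archetype truncation induces, measurement drift,
coding-system semantics, censoring beyond the eligibility flag. Passing
tests therefore demonstrate the pipeline's correctness and its behaviour
under planted structure, not performance on real cohort data.

## Preprocessing

All quantiles are linear-interpolation (R type 7). Winsorization clips to
the 1st/99th percentiles; note it is an exact fixed point only when the
percentile ranks (n−1)q land on order statistics (n = 101, 201, …) —
otherwise a second pass moves the cutoffs inward by less than one
inter-observation spacing, which is why the tests assert exact idempotence
at n = 301 and a drift bound elsewhere. Yearly snapshots: year k before
the index date is the 365-day bin ending k·365 days before it; continuous
codes take the median over the 11 × 30-day months farthest from the index
date (the 35 leftover days adjacent to the index-date side are the
time-gap and are excluded); medication codes become an any-prescription
flag over the whole bin. Features are dropped at > 50% training-row
missingness or near-zero variance (frequency ratio of the two most common
values > 95/5 **and** unique values < 10%, the conventional thresholds).
Median imputation is fitted on training rows only. Metabolite absolute
concentrations are square-root transformed (ratios pass through); protein
panels drop subjects whose mean expression falls outside the
[0.2, 99.8] percentiles of per-subject means.

## Risk model

Nested 5×5 stratified cross-validation; filters and imputation are
refitted inside every training partition, including each inner fold, so no
held-out statistic reaches a model that predicts the held-out subject. The
grid search trains each η once to the maximum round count and scores
truncated predictions for every round-count candidate (boosting is
sequential, so a truncated model equals one trained shorter); ties break
toward smaller η, then fewer rounds. The booster runs single-threaded with
derived seeds, which makes every artefact byte-reproducible. NPV is
TN/(TN+FN). The 95% interval is a t-interval with 4 df across the five
outer folds; the interval construction is a convention choice, not an
inferential claim. Permutation nulls shuffle labels *before* fold
construction and re-run the entire pipeline per repetition.

## Explanation

TreeSHAP attributions come from the booster's native path-dependent
algorithm (`pred_contribs`), on the log-odds scale, with additivity
(base + Σφ = logit(p)) checked to 10⁻³ for every subject. Two modes exist:

- **out-of-fold** (default): each subject is attributed by the model that
  excluded it; used for rankings, waterfalls and the additivity contract.
- **pooled**: the mean attribution over all five fold models; used for
  clustering. The out-of-fold map assigns near-identical subjects to five
  systematically offset attribution vectors (one per fold model), and a
  graph clusterer will happily recover that fold partition instead of the
  biology — pooling removes the offsets at the cost of a small optimism
  that is irrelevant for unsupervised structure.

The "risk without feature j" counterfactual is
sigmoid(logit(p) − φⱼ): attribution arithmetic, not a causal estimate.

## Subgrouping

PCA to 10 components (signs fixed by making each component's
largest-magnitude loading positive), SNN graph on k = 20 Euclidean
neighbours (self included), Jaccard edge weights, pruning below 1/15,
Louvain at each resolution in {0.3, 0.4, 0.5, 0.6, 0.8, 1.0} with a seeded
RNG. Communities smaller than 5 subjects — far below the neighbourhood
scale, and unscorable by the subsampled silhouette — are absorbed into the
nearest cluster by centroid; labels are renumbered by decreasing size.

The resolution score divides the size-weighted mean of per-cluster median
subsampled silhouette widths (30 subsamples of 80%) by one minus the
size-weighted median of per-cluster F1. "Prediction values" are read as
per-cluster F1 — the balanced summary of the per-cluster PPV and
sensitivity that the scoring step computes — and the weighted median is the
lower weighted median, except that an exact half-weight boundary averages
the two adjacent values (this is what makes the worked score instance
{sizes 2,2; silhouettes 0.5, 0.3; F1 0.8, 0.4} evaluate to exactly 1.0). A
weighted-median F1 of 1 is capped to +∞. Selection takes the highest
score; ties prefer more clusters, then lower resolution; the full score
table is retained for inspection.

## Rules

One-vs-rest per cluster on the original (imputed) input values: 10
bootstrap bags, Gini classification trees of depth 5; every root-to-node
path ending in a majority-positive node is a candidate; same-feature
conditions are intersected; out-of-bag precision (> 0.5) and recall
(≥ 0.2) filter candidates. Deduplication compares condition sets up to 7
terms with thresholds rounded to 6 significant digits; the keeper takes
the best (precision, recall) and a tree count equal to its distinct source
trees. Selection is a total order: tree count, precision, recall, fewest
conditions, rule text. Missing values fail a condition; holdout subjects
with missing values in any rule variable are excluded before assignment
(a non-firing mode is available behind a flag).

## Holdout validation and markers

Assignment categories (unique / ambiguous / unassigned) partition the
population exactly; ambiguity of any multiplicity resolves to the matching
cluster with the highest discovery case percentage, then the larger
discovery cluster, then the lowest id. Concordance is squared Pearson
correlation of per-cluster case fractions and size fractions across
populations; clusters with no assigned holdout member are excluded and
reported.

The marker test is a likelihood-ratio χ²(1) between nested logistic
regressions (membership ~ covariates + feature vs membership ~
covariates), with sex as the default covariate, no minimum-detection
filter, both directions reported, and Bonferroni correction within each
cluster. The fits use a damped Newton solver vectorised across features
(it matches statsmodels' GLM log-likelihoods to machine precision in the
test suite and a brute-force optimizer oracle independently); fits that
exhaust the iteration budget — e.g. complete separation — are flagged, and
their p-value uses the likelihood-ratio statistic at the last iterate.

## Study configurations and problem sizes

The validation studies fix their conditions in `riskcarver.studies`:

- **Analytic AUC**: one N(0,1) feature, β = 1.19, n = 5000, nested 5×5 CV
  with a compact grid (η ∈ {0.1, 0.3}, rounds ∈ {50, 100}); the target is
  Φ(1.19/√2) ≈ 0.800.
- **Permutation null**: β = 1.0, n = 2000, 20 permuted repetitions with a
  single grid point.
- **Four archetypes** (subgroup recovery and holdout concordance): four
  rare binary flags (0.2% background rate, prevalence 0.12, risk shift
  2.0), n = 4000. The flags behave like rare diagnosis/prescription codes;
  rare background carriage keeps coincidental multi-flag profiles — which
  would form their own small clusters — negligible. Continuous no-effect
  covariates are excluded from this panel because their attribution noise
  fragments the background into spurious clusters; with
  `min_child_weight = 50`, a 12%-prevalence flag needs roughly 200+
  carriers in a training partition, hence n = 4000.
- **Five rules** (rule recovery): three single-condition rules in the far
  tails (|t| ≥ 2.4, prevalence 0.10) and, listed first so nothing erodes
  their membership, two conjunctions whose conditions each fire naturally
  for ~12% of subjects (prevalence 0.07). The balance is deliberate: a
  conjunction condition must fire for more non-members than there are
  members, or a single forced condition already forms a majority-positive
  node and can win selection on its own; at the same time cross-rule
  natural satisfaction must stay rare, or first-match relabelling caps the
  later rules' precision. Threshold recovery is judged on the conditional
  margin (subjects satisfying the rule's other conditions) within a
  10-observation window, because a bootstrap bag thins the sample and a
  tree's split can sit a few observations beyond the full-sample gap.
- **Markers**: 200 proteins, 14 clusters, n = 1500; power case plants a
  +2 SD shift in one cluster; the null study repeats the full test battery
  over 20 seeds and compares the mean count of significant (cluster,
  protein) pairs with the per-cluster family-wise budget 0.05 × 14.

The full-pipeline configuration (`pipeline_config`) runs the
four-archetype study end to end, including a synthetic protein panel with
one planted marker, in ~35 s on one CPU; `scripts/acceptance.py` runs all
studies in about two minutes.

## Known limitations

- Louvain's behaviour on near-duplicate points depends on SNN pruning;
  the min-size absorption step is a pragmatic guard, not a principled
  model of tiny clusters.
- The cluster score is undefined for a single-cluster solution (silhouette
  needs ≥ 2 clusters); such solutions are marked invalid rather than
  scored.
- The LR marker test relies on the asymptotic χ²(1) reference; at very
  small cluster sizes the per-cluster error control is approximate.
- Rule induction assumes a fully imputed table; rule *application* treats
  missing values as non-firing, and validation excludes subjects with
  missing rule variables, so the two stages see different missingness
  conventions by design.
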