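# Methods

This note documents the models and estimators implemented in `plasticome`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions adopted where the
design was genuinely open.

## Study design assumed

Two diet arms (low-carb, low-fat) of obese but otherwise healthy adults,
randomised, with *ad libitum* macronutrient restriction.  Each subject
contributes up to three stool samples on consecutive days before the diet
("BL") and again about ten weeks in ("W10"), profiled by 16S rRNA amplicon
sequencing into an ASV (exact amplicon sequence variant) count table with a
maximum-likelihood phylogeny over the ASVs.  Outcomes are the 12-month
percent weight loss, categorised as unsuccessful (US, <3%), moderately
successful (MS, 3–10%, boundaries inclusive) and very successful (VS,
>10%), and dietary phenotypes from 24-hour recalls at baseline, 3, 6 and
12 months: adherence = 100 − mean on-diet restricted-component %kcal, and
change = baseline − mean on-diet restricted %kcal.  The restricted
component is fixed by arm (carbohydrates on low-carb, fat on low-fat).

## Plasticity

Plasticity is treated as a subject-level trait: the expected β-diversity
between a subject's own samples.  Two estimands:

* **Daily plasticity** within a window. When a subject provided three
  samples only consecutive-pair distances (in collection order) enter the
  mean — the first-vs-third pair would confound slow drift with daily
  turnover. "Consecutive" means successive in collection order, not
  calendar-adjacent, so subjects with samples a few days apart remain
  usable. The same estimator is used in the W10 window.
* **Plasticity over ten weeks**: the mean over the full bipartite set of
  BL × W10 pairs.

Subjects contribute one value per (pairing, metric); all group tests and
correlations operate on these subject means. Group comparisons use the
two-sided Wilcoxon rank-sum test, exact when the combined sample size is
≤20 with no ties (group sizes here are ~9–15, so exactness is affordable),
otherwise the normal approximation with tie and continuity corrections.
Correlations are Spearman's rank correlation; for ≤8 pairs the p-value is
an exact enumeration over all pairings (beyond that, enumerating n!
pairings buys no inferential precision over the t approximation, which is
used instead).

Distances for plasticity default to the **proportion** scale (relative
abundances). The asinh-normalised scale is reserved for ordination, where
the variance-stabilising transform prevents uniformly abundant taxa from
dominating Bray-Curtis; either analysis can use either scale via the
`scale` argument.

### The five β-diversity metrics

Jaccard and unweighted UniFrac see presence/absence (membership turnover);
Bray-Curtis, Jensen-Shannon divergence and weighted UniFrac see abundances
(structure turnover). Conventions:

* Jensen-Shannon uses log base 2 so the divergence (not its square root)
  lies in [0, 1], commensurate with the other bounded metrics.
* Weighted UniFrac is the **normalized** variant, bounded [0, 1], so
  metrics are comparable side by side.

## Rarefied phylogenetic diversity

Faith's PD is the total branch length spanned by the tips observed in a
sample (root-to-tip paths; the root's own subtending edge, if present in
the file, is excluded by convention).  Because PD grows with depth, samples
are compared at a fixed interpolated depth *m* via the exact expectation
under subsampling without replacement: a branch with *n_b* of the sample's
*N* reads below it is retained with probability 1 − C(N−n_b, m)/C(N, m),
and E[PD(m)] sums branch lengths weighted by these hypergeometric
probabilities.  Binomials are evaluated with log-gamma differences;
extrapolation (m > N) is refused, and shallow samples are reported missing.
The default depth of 11,000 reads reflects a cohort whose minimum
post-filter library was that size; any m can be passed.

## Phylogenetic ASV clustering

A maximum-likelihood 16S tree is not ultrametric, so "cutting the tree at
height h" needs a convention: we agglomerate tips by **average linkage on
patristic (tip-to-tip path) distances** and cut the dendrogram at merge
height h.  This reproduces hclust-style semantics without requiring
ultrametricity; the linkage is configurable and ties are made deterministic
by sorting tips lexicographically.  The default h = 0.1
substitutions/site corresponds, for 233 bp V4 amplicons with a median
within-cluster difference of 7.5 bp, to 96.8% sequence identity
(100·(L−d)/L) — the range typically used to delimit genera.  Cluster
counts are column sums, so per-sample totals are conserved exactly.

The prevalence filter is **subject-level**: a feature counts as present in
a subject if any of that subject's samples contains it, and is retained
for a diet's contrast when present in at least ⌈0.10 · n_subjects⌉ of that
diet's subjects.

## Differential abundance

The stack adapts the limma-voom workflow to sparse 16S counts.

1. **Size factors** (poscounts, median-of-positive-ratios): the reference
   for each feature is the geometric mean of its positive counts; each
   sample's factor is the median of count/reference over its positive
   features, rescaled to geometric mean 1.  Ordinary median-of-ratios
   fails when every feature has a zero; this variant is built for sparse
   tables.
2. **asinh-voom**: y = asinh(count/size factor).  The inverse hyperbolic
   sine is defined at zero and behaves as log(2x) for large x, a better
   variance-stabiliser than log-CPM for negative-binomial-like 16S data.
   Per-feature OLS residual SDs against the design are square-rooted and
   smoothed by lowess (span 0.5, 3 robustifying iterations) against the
   feature mean of y; the trend is interpolated at each observation's
   fitted value — clamped at the trend endpoints and floored at 1e-4 to
   avoid the known weight blow-up at extreme means — and inverted to the
   fourth power to give precision weights.
3. **Consensus within-subject correlation**: repeated daily samples form
   subject blocks with compound-symmetry correlation ρ.  Per feature, ρ is
   estimated from weighted-OLS residuals by moment matching that corrects
   the hat-matrix shrinkage: with P the within-block pair indicator and H
   the feature's hat matrix, E[e′Pe] and E[e′e] are both linear in ρ
   (coefficients tr(P(I−H)), tr(P(I−H)P(I−H))), so the observed ratio is
   inverted for ρ.  The naive cross-product/variance ratio is biased
   toward zero by the projection — enough to visibly deflate GLS standard
   errors — while the corrected estimator recovers a true ρ of 0.5 to
   ±0.01 on Gaussian data at the design sizes used here.  The consensus is
   tanh(trimmed mean, 10% per tail, of atanh ρ_g), clipped to (−0.99,
   0.99); all-singleton blocks fall back to 0 with a warning.
4. **Moderated GLS**: per feature, observations are whitened by the
   Cholesky factor of the block correlation matrix at the consensus ρ
   combined with the feature's weights, then fitted by least squares.
   Residual variances are shrunk toward an empirical-Bayes prior whose
   hyperparameters (d₀, s₀²) come from method-of-moments on log s²
   (digamma/trigamma matching; the trigamma equation is inverted by Newton
   iteration).  When the observed log-variance spread is below the
   sampling noise implied by the residual df the prior df is infinite and
   the pooled variance is used, with a warning.  The moderated t for a
   contrast uses s̃² = (d₀s₀² + d·s²)/(d₀+d) on d + d₀ degrees of freedom.
5. **Design and contrasts**: both diets are fitted jointly.  The
   categorical outcome uses a cell-means diet × success design (six
   cells; MS samples stay in the fit) plus sequencing-lane dummies, so the
   within-diet VS − US contrast is a single coefficient difference.  The
   continuous mode replaces the cells with per-diet intercepts and
   per-diet slopes on percent weight loss.  The reported logFC is the
   contrast estimate on the asinh scale (positive = higher in VS); no base
   conversion is attempted.  BH adjustment is applied per contrast over
   the features passing that diet's prevalence filter, at α = 0.05.

## Community statistics

* **P/B ratio**: per sample, summed Prevotella counts over summed
  Bacteroides counts, raw scale (the scale cancels in the ratio except for
  the pseudocount).  A pseudocount of 1 is substituted **only** when
  Prevotella is exactly zero — roughly half of subjects never detect it —
  and samples with zero Bacteroides are excluded as undefined.  Subject
  values are means over pre-diet samples; subjects are classed high at a
  ratio ≥ 0.003 (the boundary deliberately classes high, fixed and
  tested).
* **PCoA**: classical scaling (double-centred −D²/2, eigh); negative
  eigenvalues, possible for non-Euclidean dissimilarities, are dropped
  from coordinates and reported separately.
* **PERMANOVA**: Anderson's pseudo-F from the partition of squared
  distances; p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1) with 999
  permutations by default.  Whole-label permutation treats samples as
  exchangeable; with repeated measures this is optimistic, so a
  subject-level permutation (subjects carry their samples) is available
  via the `subjects` argument.

## Synthetic cohorts

The generator emulates the cohort's statistical structure, not its biology:

1. global composition p ~ Dirichlet(0.5) over n taxa (sparse, skewed);
2. subject baseline log-composition = log p + N(0, σ_between²) per taxon;
3. day d: softmax(baseline + ε_d), ε_d ~ N(0, σ_plasticity(subject)²)
   i.i.d. per taxon per day — **exchangeable perturbations about a subject
   centroid, not a random walk**, so daily plasticity is a well-defined
   subject trait;
4. W10 adds δ · v_diet · (subject dietary change / arm mean change) on the
   log scale, v_diet a fixed unit direction per arm;
5. VS subjects carry signed log-scale effects on designated taxa (MS half
   effect), drawn from the upper abundance half — an asinh-scale effect of
   1.5 is not expressible on a taxon whose expected count is ~0;
6. counts ~ Multinomial(depth, composition), depth ~ LogNormal;
7. per-lane multiplicative taxon bias exp(N(0, σ_lane²)) before the draw,
   giving the differential-abundance lane term something real to remove.

Defaults mirror the emulated cohort where stated: 33 subjects/arm, 3-day
windows, 1,000 taxa, depth LogNormal(μ=11.11, σ=0.43) ≈ 74,000 ± 33,000
reads, 7 sequencing lanes, US/MS/VS mix ≈ 30/40/30%.  Values the design
leaves open were fixed once at realistic levels: σ_between = 1.0 (subjects
well separated, as individualized microbiotas are), σ_plasticity = 0.4
(daily Bray-Curtis ≈ 0.2–0.3 on proportions), lane bias SD = 0.1 (mild
batch effects), Dirichlet concentration 0.5 (strong abundance skew).
Prevotella rarity is calibrated so a subject's expected total Prevotella
count across their samples is ~0.7 reads, leaving about half of subjects
with no detection at any configured depth.  One `numpy` Generator seeded
from the config drives every draw, so outputs are bit-identical per seed.

What the generator does **not** emulate: taxon-taxon interactions,
compositional correlation beyond the softmax constraint, overdispersion
beyond multinomial + lognormal subject/day effects, chimeras or any
read-level artefacts, realistic taxonomies beyond the two genera the P/B
ratio needs, and drop-out mechanisms tied to biology rather than depth.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, and calibration/power at these noise levels — not
performance guarantees on real sequencing data.

## Numerical conventions and edge cases

* Strict integer validation on count input; all-zero samples are rejected.
* Trees must be rooted (bifurcating root) with non-negative lengths; a
  root edge length is normalised to 0.
* asinh(0) = 0 by construction — the reason the transform replaces log.
* Wilcoxon exactness threshold n ≤ 20 (no ties); Spearman exact
  enumeration n ≤ 8; both thresholds are parameters.
* fcluster cut at h uses ≤ semantics (merges at exactly h are inside the
  cluster); cut h = 0 leaves distinct tips separate.
* BH flags are ≤ α on adjusted p-values; adjusted values are monotone in
  the raw ranking by construction.
* Weight-loss category boundaries (3%, 10%) class as MS; P/B boundary
  0.003 classes as high.
* Degenerate designs (rank-deficient, missing VS or US cells,
  non-estimable contrasts) raise with the offending columns named.

## Problem sizes used by the test suite

Simulation-backed checks run at desk scale: parameter recovery uses 40
subjects × 3 days at depth 10,000 over 200 taxa (5 seeds); error-control
studies use 30 subjects/diet × 2 replicate days over 200 taxa (20 null and
10 power seeds); oracle comparisons use 8–15-sample instances.  These
sizes match the emulated cohort's per-arm magnitudes while keeping the
whole suite fast enough to run on every change.

## Known limitations

* The compound-symmetry GLS treats the consensus ρ as known; with few
  subjects the uncertainty in ρ is not propagated (the same approximation
  limma makes).
* The moderated inference is asymptotically calibrated for asinh-Gaussian
  responses; extremely rare taxa (mostly zeros) violate this, and the
  prevalence filter is the main guard.
* Tree-cut clustering on patristic distances is one of several reasonable
  realisations of "cutting at height h" for non-ultrametric trees; results
  at a given h depend on the linkage convention (documented, configurable).
* PERMANOVA's sample-level permutation is anti-conservative under repeated
  measures; use the subject-level option for such designs.
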