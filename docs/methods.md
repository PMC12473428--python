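# Methods

`seedpheno` implements the statistical chain used to quantify genetic
divergence among clonally propagated genotypes from seed-imaging
(digital phenotyping) data: per-trait RCBD ANOVA with genetic-parameter
estimation, Gower/Ward/modified-location-model grouping, canonical
variate analysis of the groups, and trait-pair Pearson correlation —
plus a synthetic-trial generator with known ground truth so every
stage is testable without field data.

## Trial model and genetic parameters

Each trait is modelled as a randomized complete block design,

    Y_ij = mu + G_i + B_j + E_ij,    i = 1..g genotypes, j = 1..r blocks,

with the classical two-way (genotype + block, no interaction)
decomposition. For g = 43 and r = 4 the degrees of freedom are 3
(blocks), 42 (genotypes), 126 (residual), 171 (total). F for genotypes
is MSG/MSE on (g−1, (g−1)(r−1)) df; p-values are reported per trait
(matching the field's per-trait significance stars) with a Bonferroni
column alongside.

Genetic parameters at the genotype-mean level:

    sigma2_g = (MSG − MSE)/r        genotypic variance
    sigma2_p = MSG/r                phenotypic variance of means
    sigma2_e = MSE/r                environmental variance of means
    h2       = sigma2_g / sigma2_p  broad-sense heritability (clone level)
    CVg      = 100·sqrt(sigma2_g)/mean
    CVe      = 100·sqrt(MSE)/mean   (plot level; see below)
    VI       = CVg/CVe              variation index

**CVe convention.** Two CVe conventions circulate: plot level
(`sqrt(MSE)`) and genotype-mean level (`sqrt(MSE/r)`). The default is
plot level, so `VI = sqrt((MSG−MSE)/r)/sqrt(MSE)`; this is the
convention under which the reference trial's printed VI for cherry
sphericity (0.783) follows from its printed mean squares. The
mean-level convention is available via `cve_level="mean"` and is
exactly `sqrt(r)` times larger.

**Negative sigma2_g.** When MSG < MSE the estimate is reported as
computed (negative) with a flag; it is clamped to zero only inside h²
and CVg. Transparency over silent truncation.

Heritability here is heritability of genotype means, broad sense; no
additive/dominance partition is attempted (the genotypes are clones).

## Reference trial constants

`seedpheno.reference` carries the published per-trait ANOVA summaries
(block/genotype/residual mean squares and residual CV%) of a 43-clone
conilon coffee trial whose raw imaging data were never deposited.
These summaries are sufficient inputs for every estimator above and
serve as worked examples and acceptance anchors. Two rows of the
published tables are internally inconsistent and are reconciled only
where the generator needs self-consistent defaults (never in the
worked examples themselves):

* bean area: the printed residual MS (0.114) is inconsistent with the
  printed residual CV% (8.048) and the trait's scale; the printed
  cherry-area row carries the identical digits at 0.0114, indicating a
  decimal slip. Generator defaults derive the residual variance from
  the CV% instead of the raw MS.
* cherry irregularity: the printed genotype MS (0.0028) is *below* the
  residual MS (0.0035) yet flagged significant; defaults use h² = 0.85,
  consistent with the trial's summary statement that heritabilities
  were above 80% for almost all traits.

## Synthetic-trial generator

`simulate_phenotypes` draws the additive model directly: genotypic
effects `G_i` are multivariate normal across traits with covariance
`diag(sd_g)·Rg·diag(sd_g)` (Rg defaults to identity), block effects are
independent per trait, and residuals are multivariate normal per plot
with cross-trait correlation Re. The design is balanced by
construction and byte-identical under a fixed seed.

Default trait means come from the reference trial's group-mean
averages; default variance components reproduce the published residual
CV% and heritabilities at r = 4 (so the generator's "null" conditions
are the reference trial's own signal-to-noise regime). Default sizes
are g = 43, r = 4 — four replicates of imaged seed lots per genotype.

**Latent group structure.** Optional divergence groups are applied as
mean shifts on the genotypic effects (groups act on genotypes, the
level the grouping chain clusters). The groups lie on a single
morphological gradient: consecutive group centers differ by `delta`
within-group standard deviations (`sqrt(sigma2_g + sigma2_e/r)`) on
*every* trait, with a random sign per trait. The rank-one geometry is
deliberate, and it matters. In seed-morphology trials the dominant
divergence axis is an overall size/shape gradient, visible in practice
as one canonical axis carrying most of the between-group variance;
under that geometry the grouping model's log-likelihood profile shows
its largest jump at the true group count. Under full-rank (simplex)
center geometry, by contrast, each additional split removes one
orthogonal signal direction from the pooled covariance and the
likelihood increments decrease monotonically in k — the
largest-increment rule would then always answer k = 2, for any shift
size. The gradient geometry is therefore both the realistic emulation
and the regime in which the group-count rule is informative.

Membership is a seeded random partition into near-equal groups. The
reported true heritability `sigma2_g/(sigma2_g + sigma2_e/r)` excludes
the group-shift variance, so realized ANOVA heritabilities on grouped
data exceed it — group structure *is* genotypic signal.

`simulate_seed_lots` provides the image-path fixture: one superellipse
outline per genotype × replicate with genotype-level axes/squareness
and multiplicative replicate wobble; measuring the outlines with
`measure_shape` and stacking the descriptors yields a phenotype table,
closing the polygon → descriptor → ANOVA path end to end.

What the generator does **not** emulate: non-normal trait
distributions, the 50-seed averaging inside a replicate (replicates
are drawn directly at lot level), spatial field trends,
genotype-by-year interaction, and imaging artefacts. Passing recovery
tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to these real-data features.

## Divergence grouping (Ward-MLM)

1. **Profiles.** Genotype means over replicates; bean and cherry
   traits enter jointly. Profiles entering pseudo-F and the grouping
   model are range-normalized.
2. **Gower dissimilarity.** All traits are quantitative, so
   `d(i,j) = mean_t |x_it − x_jt| / range_t`, bounded in [0, 1].
   Zero-range traits are dropped with a warning.
3. **Ward linkage.** scipy's `ward` Lance–Williams update applied
   directly to the Gower dissimilarities (the Ward.D2 convention, the
   modern default). Ties resolve by scipy's deterministic
   nearest-neighbor-chain order.
4. **Grouping model.** With zero categorical variables the
   modified-location-model reduces to a k-component Gaussian model
   with group-specific means and one pooled covariance. We fit it by
   classification EM (hard assignments — published group memberships
   are hard), initialized from the Ward cut at each k: assign each
   genotype to the highest-density group, re-estimate means and pooled
   covariance (ML divisor n), repeat to convergence (max 100
   iterations). Soft EM is available via `hard=False`. The reported
   log-likelihood is the classification log-likelihood.
5. **Group count.** k* maximizes the log-likelihood increment
   `logL(k) − logL(k−1)` over k ≥ 2, ties toward smaller k. Pseudo-F
   (Calinski–Harabasz) and pseudo-T² (Duda–Hart, at the merge taking
   k to k−1 groups) are computed and reported as concordance
   diagnostics but do not enter the decision. Undefined criteria
   (degenerate partitions) are reported missing, never fabricated.
6. **Inter-group divergence.** Squared Mahalanobis distance between
   group mean vectors under the pooled within-group covariance.

Numerical choices: the pooled covariance is ridged by
`1e−8 · trace/dim · I` before inversion (configurable); a group that
empties during CEM is re-seeded with the point farthest (Mahalanobis)
from its assigned mean, never stealing from a singleton group, with a
warning; `kmax` defaults to `min(10, n−1)`; the likelihood profile is
checked for decreases, which are logged as diagnostics.

## Canonical variate analysis

Traits are standardized to z-scores; within-group (W) and
between-group (B) scatter matrices are formed from the group
assignment, and the axes are the generalized eigenvectors of
`B a = λ (W + ridge) a`, ordered by decreasing eigenvalue, at most
`min(traits, k−1)` axes. Coefficient vectors are scaled to unit pooled
within-group variance (`aᵀ (W/(n−k)) a = 1`) and each axis's sign is
fixed so its largest-|coefficient| trait loads positively. A trait's
"contribution" to divergence is `100·|axis-1 coefficient|`; because
the coefficients are within-variance-scaled rather than bounded, the
contribution can exceed 100 when group separation is extreme.
Eigenvalue proportions quantify how much separation each axis
carries; observation and group-mean scores support the usual
two-axis scatter plot. Analysis is run on genotype means (one point
per genotype).

## Correlation analysis

Pearson r between trait columns of the genotype-mean profiles
(n = genotypes), t-transformed significance (`t = r·sqrt((n−2)/(1−r²))`,
n−2 df) at α = 0.01 by default. Magnitude classes: null (|r| = 0),
weak (< 0.30), moderate (< 0.60), strong (< 0.90), very strong (< 1),
perfect (= 1); boundary values go to the upper class, since the
conventional open-interval definitions leave boundaries unassigned.
Per-class percentages of the C(t, 2) pairs are truncated (not rounded)
to two decimals, matching the field's summary convention (3/45 →
6.66%). The default ten-trait subset is five bean + five cherry
traits; correlations at replicate level are available by passing the
replicate pivot (labelled phenotypic rather than genotypic).

## Shape descriptors

From a simple closed polygon (or a single-component binary mask traced
to a polygon at its 0.5 level set):

* area, perimeter: polygon surface and contour length;
* max/min diameter: longest/shortest chord through the centroid,
  evaluated on 360 equally spaced directions (not Feret calipers);
* circularity: area over the area of the circle with the same maximum
  diameter — 1 for circles, sensitive to elongation, insensitive to
  contour roughness (the classic 4πA/P² would not be);
* sphericity: P²/A, equal to 4π ≈ 12.57 for a circle;
* rectangularity: area over the minimum-area enclosing rectangle;
* irregularity: convexity deficit `1 − P_hull/P` — zero for convex
  outlines, growing with roughness. A documented proxy: instrument
  vendors use unpublished contour-irregularity measures, and no public
  formula exists;
* corner count: curvature maxima on an arc-length-resampled contour
  (512 points), Gaussian-smoothed with σ = 1% of the contour length,
  peaks above 2× the median curvature with a minimum separation so a
  rounded corner is counted once. Also a documented proxy; all
  constants configurable.

Dimensionless descriptors are scale-invariant; raster and polygon
measurements of the same shape agree within a discretization error
that shrinks with resolution (verified in tests).

## Problem sizes and runtime

The analysis scripts and test suite run at the study's own scale — 43
genotypes × 4 replicates × 17 traits — where one full grouping chain
takes well under a second. The statistical recovery checks use 100
seeded runs of the 43 × 4 chain, 200 Monte-Carlo heritability draws at
g = 200, and ~13,500 null correlation pairs, sizes at which the
binomial/Monte-Carlo error of each checked rate is several times
smaller than its acceptance margin.

## Known limitations

* The grouping likelihood is a classification (hard-assignment)
  likelihood; it is not comparable across software that reports
  mixture likelihoods, and its absolute scale depends on the
  range-normalization of profiles.
* The largest-increment group-count rule is informative only when the
  group structure is low-rank relative to the trait space (see the
  generator discussion); with isotropic structure it saturates at
  k = 2.
* Irregularity and corner count are proxies; they agree with the
  published descriptors in spirit (convexity/sharpness) but not
  necessarily in value.
* No multiple-testing correction is applied to the correlation matrix
  (deliberately, matching field convention); the Bonferroni column in
  the ANOVA table is informational.
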