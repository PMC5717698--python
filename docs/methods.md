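# Methods

`clinepop` implements a range-wide clinal-genomics workflow for biallelic
SNP panels from riverine populations of two independently evolving lineages
(the motivating system is Atlantic salmon on the North American and European
sides of the Atlantic). This note records the models, the conventions and
tie-breaks, the synthetic-data contract, and what the tests do and do not
establish about real data.

## Data model and filtering

Genotypes are stored as counts (0/1/2) of a *counted* allele per locus, with
an explicit missing code. The counted allele is the numerically smaller
allele code in the source Genepop file — a deterministic, dialect-independent
choice. Polarity never matters downstream: the clinal classifier uses the
absolute fitted frequency change, and every statistic here is invariant
under p → 1 − p (tested).

Locus filters run in a fixed order — monomorphic, then pooled minor-allele
frequency < 0.01, then pooled missing fraction > 15% — and each removed
locus is reported once, under the first rule it violates, so the removal
report partitions the removed set. Boundary loci (MAF exactly 0.01,
missingness exactly 15%) are retained: the thresholds exclude strictly
worse loci only. Both lineages are pooled for filtering, mirroring a single
pass over a merged panel.

## The cline classifier

For locus ℓ in one lineage, with counted-allele count k_j out of m_j alleles
in population j at latitude x_j, the model is

  k_j ~ Binomial(m_j, p(x_j)),  logit p(x) = a + b·x,

fitted by iteratively reweighted least squares (tolerance 1e-8, ≤ 100
iterations). The binomial count — not the bare frequency — is the response,
so small samples carry proportionally less weight. The classifier statistic
is the fitted range Δp = |p̂(x_max) − p̂(x_min)| evaluated on the fitted
curve at the lineage's observed latitude extremes; measuring on the curve
rather than on raw endpoint frequencies makes Δp robust to single-population
noise. A locus is clinal when Δp strictly exceeds the threshold (default
0.40; Δp = 0.40 exactly is not clinal). No slope-significance filter is
applied by default; an optional Wald-p cutoff exists but is off.

Perfect separation (southern populations fixed for one allele, northern for
the other) sends |b| to infinity with an essentially flat likelihood. The
slope is capped at |b| ≤ 50 per degree, the fit is flagged, and the
intercept is profiled with the transition placed at the midpoint of the gap
between the low- and high-frequency populations — a deterministic tie-break
among the equally likely intercepts. Capped fits count as clinal (they are
extreme clines); monomorphic loci give a degenerate flag with Δp = 0 and are
excluded from classification.

The threshold-scan diagnostic reports count(t) = #{ℓ : Δp > t} over a grid
and a knee estimate. The knee is the interior grid point falling furthest
below the chord joining the grid endpoints after normalizing both axes (the
standard elbow construction). A raw discrete second difference of count(t)
was considered and rejected: it peaks where the neutral bulk's density
curves fastest, inside the bulk, rather than where the decline gives way to
the plateau of genuine clines. The knee is a diagnostic only; the default
classification threshold stays at 0.40.

## Overlap of clinal architectures

With n₁ and n₂ clinal loci detected in the two lineages out of a common
panel of N, the chance-shared count is Hypergeometric(N, n₁, n₂), mean
n₁n₂/N. The permutation test draws both subsets uniformly without
replacement in each iteration and reports the *strict* exceedance tail
P(X > k_obs); the exact hypergeometric tail (scipy's log-gamma survival
function) is reported alongside and the two agree within Monte-Carlo error
by construction (tested at 3 SE). Strict exceedance is the default
convention because, at the reference configuration N = 1773, n₁ = 84,
n₂ = 195, k_obs = 12 (expected overlap 9.24), the strict tail is ≈ 0.124
while the inclusive tail P(X ≥ 12) is ≈ 0.205 — only the strict tail is on
the scale of the published probability (~0.11). Both tails are always
reported so the convention is never hidden.

## Population structure

**F_ST.** Weir & Cockerham's (1984) θ̂ from per-locus variance components
a (among populations), b (among individuals within populations), c (within
individuals), with the heterozygosity correction; multilocus aggregation is
the ratio of sums Σa/Σ(a+b+c), the standard convention. Negative per-locus
values are retained so the sums stay unbiased; loci monomorphic across all
populations are 0/0 and excluded. The suite checks the implementation
against an independently coded transcription of the component formulas at
1e-10, and checks that Balding–Nichols panels recover the generating θ
within ±0.02.

**AMOVA.** Two strata above the individual: groups (lineages) and
populations within groups. Sums of squares are squared-Euclidean on the
allele-count genotype vectors (missing entries mean-imputed per locus) —
a haplotype-free convention, since phase is unavailable; the SS partition
is exact (tested at 1e-10). Variance components come from the nested-ANOVA
expected mean squares with unequal-size coefficients; F_CT, F_SC, F_ST are
the usual ratios (guarded to 0 when a denominator vanishes, e.g. the
saturated no-within-variance case). Significance: permuting whole
populations among groups for F_CT, individuals among populations within
their group for F_SC; p = (exceedances + 1)/(n_perm + 1). Note the
permutation granularity: with g populations per group there are only
(2g choose g)/2 distinct partitions, so small designs cannot produce small
p-values.

**Isolation by distance.** OLS of linearized F_ST/(1 − F_ST) on pairwise
distance over unordered pairs; significance by a one-sided (greater) Mantel
permutation of population labels — one-sided because isolation by distance
is a directional hypothesis. Pairs with F_ST = 1 are excluded with a
warning.

## Clustering coefficients and geographic models

`dapc_membership` follows the DAPC recipe at K = 2: locus-mean imputation,
centering, PCA retaining the components that reach 80% explained variance
capped at n/3 (the usual overfitting guard; the retention rule is a package
choice), K-means with 20 seeded restarts on the retained components, then a
linear discriminant whose posterior membership probabilities are averaged to
population level. Averaging (rather than modal assignment) is the package's
choice. Orientation — and hence K-means label switching — is resolved by
`standardize_south_north`: flip the sign if the coefficient correlates
negatively with latitude, then min–max scale to [0, 1]. A zero correlation
with non-constant input is a genuine tie, broken so the northernmost
population lands on the high side of the scale; constant input is an error
(no orientation exists). STRUCTURE and SPCA are deliberately not
re-implemented; their coefficient tables enter through the same
standardization via a `population,coefficient,method` CSV contract.

`fit_logistic_cline` models standardized coefficients y ∈ [0, 1] against a
single predictor through μ(x) = logit⁻¹(α + βx), maximizing the
Bernoulli-form quasi-likelihood Σ y log μ + (1−y) log(1−μ) by IRLS
(responses exactly 0/1 are shrunk by ε = 1e-6 to keep the likelihood
finite). The quasi-binomial treatment of continuous [0, 1] responses is the
package's convention for a "generalized logistic regression" of
coefficients; a beta regression would be the main alternative and would
change the likelihood scale but not the fitted curve materially. Reported
per model: the inflection x* = −α/β (the predictor value where the curve
crosses 0.5 — the estimated north–south divide), AIC with exactly 2
parameters (dispersion not counted), McFadden's pseudo-r² = 1 − logL/logL₀
clamped to [0, 1], and a two-sided Wald p for β. The predictor is
internally standardized for conditioning and the parameters mapped back, so
an affine predictor transform x → cx + d maps x* → cx* + d and leaves AIC
and pseudo-r² unchanged (tested). One predictor per model; ranking across
predictors is by AIC, ties by pseudo-r² then name.

## Spatial stage

Least-cost marine distances run on a regular lat/lon raster with land
impassable. The water-cell graph uses 8-neighbour steps plus knight moves
(each knight move requires its two intermediate cells to be water, so paths
cannot thread a one-cell land barrier), with great-circle edge weights;
shortest paths by Dijkstra. Knight moves matter because lat/lon cells are
anisotropic away from the equator: with 8 neighbours alone the grid
overshoots straight-line routes by up to ~13% at 50–60°N, with the extended
stencil the overshoot stays under 5% at the default 0.1° resolution. Plain
8-neighbour mode remains available (`knight=False`) and is what the
brute-force enumeration oracle in the suite checks. River mouths snap to
the nearest water cell within 3 cells; failure to snap or a disconnected
pair is an error, never a silent fallback.

NMDS re-projects the distance matrix to 2-D Cartesian coordinates
(scikit-learn SMACOF with nonmetric monotone regression, Kruskal stress-1,
several seeded starts, coordinates re-centered). Two dimensions because the
downstream consumers need planar coordinates.

## Environmental association

VIF pruning iteratively drops the predictor with the largest variance
inflation factor 1/(1 − R²) until all are below 5; exact collinearity gives
VIF = ∞ and is dropped first; ties break by column order (the earlier
column survives). RDA centers the population × clinal-locus frequency
matrix Y (population frequencies, not individual genotypes — consistent
with the population-level design of every other stage), z-scores X by
default, optionally residualizes Y and X on conditioning covariates
(partial RDA), and fits by least squares. The global test permutes rows of
the (residualized) response; marginal type-III term tests permute
reduced-model residuals — the standard constrained-ordination scheme.
Partial Mantel correlates the off-diagonal residuals of two distance
matrices after matrix regression on a control, with two-sided significance
from joint row/column permutations of the first matrix. The simple Mantel
statistic is cross-checked against scikit-bio's implementation in the
suite.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: two lineages of 74 and
60 populations spanning 46–61°N and 43–70°N, 30 individuals each, 1773
loci, clinal fractions 4.7% and 11% with exactly 12 loci clinal in both
lineages, drift θ = 0.110 and 0.089, planted cline range 0.8 around
inflections drawn near 53.3°N and 59.9°N (sd 2°, steepness 1.5°), 5%
missing genotypes, and climate covariates affine in latitude with
weather-station-scale noise.

Neutral loci follow the Balding–Nichols model — population frequencies
Beta-distributed around an ancestral π ~ U(0.05, 0.95) with the Beta
parameterized by θ — chosen because it delivers a target F_ST analytically.
Clinal loci get the logistic expected frequency at the population's
latitude plus the same Beta jitter at θ/4; the milder jitter keeps planted
clines detectable and is an explicit knob (`theta_clinal_factor`).
Genotypes are Hardy–Weinberg binomial draws; missingness is i.i.d. All
randomness flows from one seed and identical configurations are
byte-identical (tested). The truth ledger records every locus's class and
parameters and is the acceptance surface for recovery tests.

Deliberately not modelled: coalescent ancestry and shared drift history,
linkage disequilibrium between loci, selection dynamics through time,
secondary contact, and the ascertainment bias that depresses observed
heterozygosity on one side of a real two-array panel. Consequently the
generator's realized global F_ST slightly exceeds the neutral θ (clinal
loci add among-population variance — the same direction as in real data,
where clinal loci show elevated F_ST), and the two lineages have similar
Ho. Passing recovery tests therefore shows the estimators and the
classifier work under drift + clines + missingness; they do not certify
behaviour under LD, ascertainment or shared demography.

## Problem sizes in the suite

The suite exercises the classifier-recovery check at 60 populations × 30
individuals × 1000 loci over 10 seeds, the overlap test at the full 100,000
iterations, inflection recovery over 100 seeds, and the permutation-null
calibrations over 200 seeds at 99 permutations with small panels (the
calibration property is a property of the test construction, not of panel
size). The analysis drivers under `analysis/` run the full 1773-locus,
134-population panel end to end; the isolation-by-distance stage
subsamples 20 populations per lineage for the pairwise-F_ST matrix, whose
cost grows quadratically in populations while the regression is already
stable at that size.

## Known limitations

- The AMOVA permutation p-values are coarse for designs with few
  populations per group (partition granularity, above).
- The quasi-binomial likelihood for coefficient models is a working
  convention; AIC values are comparable across predictors within this
  package but not against other likelihoods.
- Least-cost distances assume a binary water/land cost surface; no
  depth-weighted costs and no ellipsoidal corrections beyond great-circle
  edges.
- The Genepop reader supports the dialect documented in `genio` (2- or
  3-digit codes, POP-delimited, label-comma lines); it is not a validator
  for arbitrary Genepop variants.
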