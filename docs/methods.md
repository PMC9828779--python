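# Methods

This note records the models implemented in `contactzone`, the
parameter choices that matter, and what the synthetic test surface does
and does not establish about real data.

## Morphometrics

Landmark configurations (2-D) are aligned by generalized Procrustes
analysis: translation removed, each configuration scaled to unit
centroid size, and rotations solved per configuration per iteration by
2-D SVD restricted to proper rotations (det = +1).  Reflections are
never introduced during alignment; mirrored configurations (left wings
digitized in place of damaged right wings) must be flipped explicitly
first, which is how the digitization workflow the package models
operates.  Iteration stops when the consensus moves less than `tol`
(default 1e-8 RMS) or after `max_iter` (100).  Full Procrustes scaling
(per-iteration size optimization) is deliberately not used; unit
centroid size matches the standard geometric-morphometrics toolchain.

Size correction regresses every trait column on measured wing length
(distance between landmarks 1 and 4 in original units) and keeps OLS
residuals.  PCA operates on the sample covariance (n−1), no variable
scaling (Procrustes coordinates share units), components signed so the
largest-magnitude loading is positive — this makes score signs, and
hence fitted cline orientations, reproducible.

The "orange spot" trait block is a configured landmark subset
(`spot_landmarks`, 1-based indices into the wing configuration); the
synthetic wing template reserves landmarks 12–23 for a 12-point spot
ring and the pipeline defaults to that subset.

## Species assignment

A two-class Fisher discriminant is trained on genotype-labelled
specimens using the leading PC scores (components covering ≥95%
variance) of each trait block, concatenated.  Weights are
S⁻¹(μ_A − μ_B) with the pooled covariance ridge-stabilized
(λ = 1e-8·trace/d) because Procrustes coordinate blocks are
rank-deficient (4 degrees of freedom are consumed by alignment).
Priors default to training frequencies.  Posteriors are the logistic
of the prior-adjusted discriminant score.

Low-confidence assignments are removed with a per-class region: keep a
specimen iff its squared Mahalanobis distance to its assigned class
centroid is ≤ the χ² quantile at the confidence level (default 0.97)
with df = trait count.  Per-class (not joint) regions are the default
because the two species differ strongly in location; a joint region is
available by flag.  Hybrids are excluded from training, prediction,
and all phenotypic analyses.

## P-matrix comparison

θ between leading eigenvectors uses the normalized dot product with
absolute value, so θ ∈ [0°, 90°] and is invariant to eigenvector sign.
A `literal_sum` variant (dot product divided by the sum of the norms)
exists only for sensitivity checks against that alternative
normalization; it is not a cosine and is not used anywhere by default.

The between-matrix distance is the affine-invariant Riemannian metric
√Σ ln²λᵢ over generalized eigenvalues — symmetric, zero iff equal, and
invariant to any common invertible linear transform.  Near-singular
inputs receive a ridge of 1e-8·trace/d.  A mean-vector Mahalanobis
option (pooled-covariance distance between group means) is provided
because "Mahalanobis distance between matrices" is used ambiguously in
the field.

Significance: each population is resampled with replacement (same n);
the null distribution is the statistic between two **independent**
bootstrap replicates of the same population.  Under no difference the
observed two-sample statistic carries the sampling noise of both
estimates, and the replicate-pair null reproduces exactly that
variance; the alternative replicate-vs-point-estimate null
(`null="point"`) captures only single-estimate noise and empirically
inflates the false-positive rate to ~17% where the pair null sits at
~4–5% at the dual criterion.  A comparison is flagged significant when
the observed statistic exceeds the 95th percentile of **both**
populations' nulls; the p-value is the larger exceedance fraction.
Results are bit-reproducible given (seed, n_boot).

## Cline fitting

The mean function is
y_L + (y_R − y_L) / (1 + exp(−4(x − c)/w)); the 4/w parameterization
makes w the conventional cline width (inverse of the maximum slope for
a 0→1 cline), so a "35 m" width means the same thing for every trait.
Residuals are homoscedastic Gaussian.  For fixed (c, w) the likelihood
is maximized in closed form over (y_L, y_R, σ), reducing the search to
two dimensions; multi-start L-BFGS-B (centers on deciles of x, widths
log-uniform, seeded jitter) handles the multi-modality of the
likelihood in c.  Bounds: c within the observed x range, w in
(width floor, x range).  The width floor is 1 m (0.001 km), keeping
the likelihood finite on perfectly separated data; a fit at the floor
carries a boundary flag meaning "width unresolved below sampling
resolution".  AIC (k = 5) selects between the sigmoid and a constant
model (k = 2).  Scores are min–max rescaled to [0, 1] before fitting.

Profile-likelihood CIs: the set of fixed center (or width) values whose
profile log-likelihood is within χ²₁(0.95)/2 = 1.9207 of the maximum,
the other parameter re-optimized, endpoints by bisection to 1e-4 km;
a profile that never crosses the cutoff inside the parameter bounds
yields a one-sided interval with a boundary flag.  Coverage was checked
by simulation (c = 9, w = 0.2 km, σ = 0.1, n = 400): the 95% interval
covers the generating center at its nominal rate within Monte-Carlo
tolerance.

## Sliding-window scan

Within each species, individuals are ordered by distance from the
point of contact (the fitted genomic cline center by default).  The
reference set is the 30 individuals furthest from contact on the
species' own side; windows of 30, stepped by 10, march away from
contact over the remaining individuals (partial final windows are
dropped) and are compared to the reference by bootstrap θ and matrix
distance.  Before the scan, a local PCA outlier filter removes
individuals outside the 95% χ² region on the components explaining
≥95% variance — guarding against mis-assigned specimens contaminating
window covariances.  The trend test is OLS of the window statistic on
mean distance, species, and their interaction, with the bootstrap
significance state as an additive covariate; this is a fixed-effect
stand-in for a mixed model with significance state as a grouping
factor, adequate for the handful of windows a transect yields.

## Variant filter and hybrid detection

Filter order: non-biallelic sites dropped; genotypes masked when
GQ ≤ 20 or depth outside [5, 30] (per-entry when depth is present);
sites with > 60% missing entries dropped; minor allele frequency
< 0.04 dropped.  Masking precedes the missingness test — the
conservative ordering when the source lists rules without an order.
Losses are reported per rule.

Genotype PCA mean-imputes missing dosages per site.  Diagnostic sites
are those with between-panel allele-frequency difference ≥ 0.9.  An F1
candidate needs hybrid index in [0.4, 0.6] **and** interspecific
heterozygosity ≥ 0.85; first-generation backcrosses (expected index
0.25, het 0.5) fail the heterozygosity test and are called `other`.
These two thresholds are implementation choices (exposed in the API):
a true F1 is heterozygous at every diagnostic locus, so 0.85 leaves
slack for genotyping error without admitting backcrosses.

## Niche overlap

Environmental ordination is a PCA of standardized variables pooled
across groups; niche space is the first two axes.  Densities are grid
KDEs: a 2-D histogram on an R×R grid (R = 100) spanning the background
extent, smoothed with a Gaussian kernel whose absolute bandwidth comes
from Silverman's rule on the background — concentrated occurrence
clouds are therefore smoothed with the same kernel as their background
rather than their own, and the bandwidth is floored at one cell.
Occurrence density is divided by background density on occupied cells,
clamped at the 99.9th percentile, and renormalized.
D = 1 − ½Σ|z₁ − z₂|; I = 1 − ½Σ(√z₁ − √z₂)².  The similarity test
translates group 2's occurrence cloud to a random centroid within its
background, re-truncates and renormalizes, and recomputes overlap;
p = (1 + k)/(n_rep + 1) in the requested direction ("lower" asks
whether niches are less similar than random relocation).

Variable selection drops the highest-VIF variable until all VIF ≤ 10,
then resolves remaining pairs with |r| > r_max by dropping the member
with higher mean absolute correlation, ties broken by column order.

## Synthetic transect generator

The generator is the study-design model: positions uniform on a
14.58 km transect; species identity a Bernoulli draw from a sigmoid
centered at 9.0 km with width 0.2 km (a `hard_split` flag yields the
fully disjoint arrangement); 23-landmark wings and 11-landmark
genitalia built from stylized templates with species mean shapes offset
by 0.06 template units along a fixed direction and multivariate-normal
shape noise whose leading eigenvectors differ between species by a
configurable angle (default 60°) over a 10:2:1 spectrum scaled to
landmark units (leading shape SD ≈ 0.01, so the mean offset is ≈6
within-species SD — the separation regime in which a discriminant
assigns ≥97% of specimens correctly); digitization nuisance (random
scale ~N(300, 12) px, rotation ~N(0°, 5°), translation) that alignment
must remove; 60 diagnostic SNPs fixed between species plus 240
background SNPs with shared Beta(2,2) frequencies, 2% missingness,
Poisson(15) depth and uniform GQ in [15, 99); F1 hybrids at rate
3/464, placed within 0.25 km of the contact, heterozygous at every
diagnostic site, landmark means at the parental midpoint, and no
backcrosses; seven environmental gradients (logistic in space, width
4 km) centered near 3.0 km — west of the species transition — plus two
deliberately collinear extras for the variable selector to prune.
All outputs are deterministic functions of one seed, and the ground
truth (cline parameters, true p_max vectors, hybrid ids) is serialized
with the data.

What the generator does **not** emulate: linkage and coalescent
structure in the genotypes (sites are independent), spatial
autocorrelation of sampling effort, measurement error in transect
positions, allometric curvature (size effects are linear), and
population structure within species.  Passing tests therefore
establish the estimators' behavior under the stated sampling model,
not robustness to those real-data features.

## Problem sizes and determinism

Simulation-based tests run at reduced but statistically meaningful
sizes chosen as the package's own test budget: bootstrap checks use
200–1000 resamples where a production run would use 10,000 (the
default), the end-to-end run uses 500 bootstrap resamples and 300
SNPs, and calibration checks use 100–200 replicates.  Every stochastic
routine takes an explicit seed; the pipeline derives per-stage seeds
from one global seed by fixed offsets, and reports are byte-identical
across reruns with the same configuration, which is also how
`run_pipeline` safely reuses a previously written report whose
configuration digest matches.

## Known limitations

- The cline width is weakly identified on sharply separated data: with
  ~460 individuals and a 0.2 km transition, samples often contain no
  intermediate individuals and the fitted width collapses to the 1 m
  floor (flagged).  Width comparisons between traits should use the
  profile CIs, not point estimates.
- The genomic cline includes F1 hybrids (by design, matching how such
  clines are fitted in practice); intermediate hybrid scores spread
  around the contact can make the genomic width exceed phenotypic
  widths even when all clines share one generating transition.
- The trend test treats windows as independent observations although
  consecutive windows share 2/3 of their members; its p-values are
  optimistic and should be read as descriptive.
- The similarity test randomizes only the second group's niche; swap
  arguments (or run both directions) for a symmetric assessment.
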