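# contactzone

Analysis toolkit for narrow secondary contact zones between parapatric
species, built around the case of two sibling alpine butterflies that
meet along a ~15 km transect and hybridize only rarely.  The package
takes landmark-based morphometrics, SNP genotypes, transect positions,
and environmental variables for the same specimens, and asks the
questions a contact-zone study asks:

- Do the species differ in multivariate phenotype, and does the
  **orientation** of phenotypic variation differ?  Phenotypic covariance
  (**P**) matrices are compared through the angle θ between their
  leading eigenvectors **p**<sub>max</sub>
  (θ = arccos |**p**₁·**p**₂|, the divergence of the "lines of least
  resistance") and through the affine-invariant matrix distance
  √Σᵢ ln²λᵢ over generalized eigenvalues, with significance from
  within-population bootstrap nulls.
- Where and how sharply do phenotype and ancestry turn over?
  Individual-based sigmoid clines
  y ~ Normal(y_L + (y_R − y_L)/(1 + e^(−4(x−c)/w)), σ)
  are fitted by maximum likelihood, where *c* is the cline center and
  *w* the width (1 / maximum slope for a 0→1 cline), with AIC selection
  against a no-cline model and profile-likelihood confidence intervals.
- Does the P matrix itself change toward the point of contact?  A
  sliding-window scan (30 individuals, step 10) compares each window
  against the individuals furthest from contact.
- Do the species occupy different environments?  Niche overlap on
  background-corrected density grids in environmental ordination space,
  summarized by Schoener's D and Warren's I with randomization
  similarity tests.

Specimens without genotypes are assigned to species by a linear
discriminant trained on genotype-labelled individuals, keeping only
assignments inside a 97% per-class Mahalanobis/χ² confidence region.
Putative F1 hybrids are flagged from diagnostic SNPs (hybrid index ≈
0.5 **and** heterozygous at ≥85% of diagnostic sites — backcrosses fail
the second test).

A first-class synthetic transect generator
(`contactzone.synthetic_data`) produces complete datasets — TPS
landmark files, a VCF, specimen/environment tables — with known cline
centers, P-matrix angles, and hybrid identities, so every stage can be
validated against ground truth.

## Worked example

```python
from contactzone import pipeline

report = pipeline.run_pipeline({
    "seed": 2,
    "simulate": {"n_individuals": 150, "n_diagnostic_snps": 20,
                 "n_background_snps": 40},
    "n_boot": 100, "n_rep_niche": 100,
})
print(pipeline.report_summary(report))
```

prints (abridged):

```
cline fits (center km [95% CI], width):
  wing_shape       9.04 [9.00, 9.05]  width 2 m
  orange_spot      9.04 [8.99, 9.05]  width 2 m
  genital_shape    9.04 [8.98, 9.05]  width 1 m
  genomic          8.94 [8.87, 9.00]  width 422 m
  environment_pc1  2.73 [2.48, 2.93]  width 4.27 km
```

All three phenotypic clines and the genomic cline center on the
generating contact at 9.0 km and are narrow relative to the 14.58 km
transect, while the environmental cline sits ~6 km west of the species
transition and is far smoother — the signature of a species boundary
that is not anchored to an abiotic gradient.  The same analysis is
available from the shell:

```
ebz simulate --preset --seed 1 --out-dir data/
ebz run --config analysis.yaml --out-dir results/
```

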