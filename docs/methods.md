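# Methods

`prsbrain` implements a cross-disorder imaging-genetics analysis: it asks
whether the regional brain-morphology signature of *genetic risk* for a
neuropsychiatric disorder (measured in a largely healthy population)
mirrors the signature of the *diagnosed* disorder (measured in
case-control studies), and whether global brain measures are causally
upstream or downstream of the disorders. Because the individual-level
cohort (a UK-biobank-style imaging cohort) and the consortium case-control
summary maps are access-restricted, the package ships a synthetic-data
generator that emulates their statistical structure with known ground
truth; every analysis stage runs identically on user-supplied tables.

## Cohort model (synthetic data)

`generate_cohort` draws, for each of `n_participants` (default 33,861,
the scale of the emulated imaging cohort):

- covariates: age ~ Uniform(45.13, 81.83) years, sex ~ Bernoulli with a
  male-female ratio of 0.9, three scanner sites, a Gaussian scan-quality
  proxy (Euler-number analogue), and 10 standard-normal genetic principal
  components. Covariates are generated independently; the analyses only
  require their marginal structure, not the joint dependence of real
  cohort data.
- one standardized PRS per disorder (13 disorders by default),
  independent standard normals.
- regional brain measures for 12 surface-area parcels, 12 thickness
  parcels and 7 subcortical volumes (bilateral hemispheres already
  combined: sums for area/volume, means for thickness). Each region is

  `intercept + covariate effects + loading * g_i + sum_d beta[d,r] * PRS_{i,d} + eps`,

  where `g_i ~ N(0, global_factor_sd^2)` is a shared latent global-size
  factor (default SD 0.5, loading 1) that induces the strong
  inter-regional correlation real morphometry shows, and
  `eps ~ N(0, noise_sd^2)` (default 1). Planted standardized effects
  `beta[d,r]` default to zero; realistic magnitudes are |beta| = 0.01-0.05,
  the order of PRS-morphology associations in population cohorts.
- global measures derived from the regions: total surface area (sum of
  SA parcels), mean thickness (mean of CT parcels), and an intracranial
  volume proxy (sum of subcortical volumes plus noise).

Diagnoses come from a liability-threshold model:
`L_d = w_g * PRS_d - w_b * z(global brain) + eps`, diagnosed iff
`L_d > threshold`. With the default weights (1, 0.5) the threshold 4.32
gives ~0.2% prevalence — the order of magnitude of severe-disorder
diagnoses (tens of cases among ~34,000) in a community volunteer cohort.
Diagnoses are drawn independently across disorders; comorbidity structure
is not modeled.

What the generator does **not** emulate: LD structure and genotypes (PRS
enter as numbers), spatial autocorrelation of cortical maps beyond the
single global factor, site-covariate confounding, non-Gaussian measure
distributions, and missing data. Passing tests therefore demonstrate the
statistical machinery is correct under the generating model, not that
real-data effect sizes would be reproduced.

## Phenotype preparation

Measures are prepared in two stages before association testing, mirroring
standard practice for biobank-scale morphometry:

1. **Residualization** on age, sex, scanner site (dummy-coded), the
   scan-quality proxy and 10 genetic PCs, via least squares. The design
   matrix is checked for full rank and collinear columns are named in the
   error. Residualization is idempotent and the residuals are orthogonal
   to every covariate.
2. **Rank-based inverse normal transformation** with Blom offsets,
   `Phi^-1((r - 3/8)/(n + 1/4))`, average ranks for ties. Blom is the
   conventional default among the offset family; the choice only shifts
   quantiles by O(1/n). Constant columns are rejected.

**Relative measures** additionally residualize each region on its
modality-matched global measure (total SA for area, mean CT for
thickness, ICV for volumes). Adjustment by residualization was chosen
over ratio scaling or a joint covariate model: it keeps the two-stage
structure, is idempotent, and makes "relative" literally "the part of the
regional measure not explained by global size". This is a design choice
of this package, not a claim about any particular study's mechanics.

**Effective number of tests.** Regional measures are correlated, so
Bonferroni over raw region counts is conservative. From the eigenvalues
`lam_i` of the inter-regional correlation matrix the package reports both

- Li-Ji: `t_e = sum_i [ 1(lam_i >= 1) + (lam_i - floor(lam_i)) ]` (default), and
- Nyholt: `t_e = 1 + (M-1) (1 - Var(lam)/M)`.

Li-Ji is the default because it attains the intuitive limits exactly
(`t_e = M` for identity, 1 for rank-one correlation). Near-integer
eigenvalues are snapped (tolerance 1e-9) so `floor` is stable at exact
multiplicities.

## Association scan and significance tiers

Each (disorder, region) pair is an OLS fit of the prepared measure on the
standardized PRS; p-values from the t distribution with n-2 df.
Covariates are handled by the prior residualization (two-stage), not
joint fitting. Three nested significance tiers:

- nominal: p < 0.05
- disease-wise: p < 0.05 / t_e
- study-wise: p < 0.05 / (t_e * n_diseases), with n_diseases = 13 by
  default (configurable).

With t_e = 22 effective cortical phenotypes this gives a study-wise
cortical threshold of 0.05/286 = 1.7e-4, and with t_e = 7 subcortical
phenotypes 0.05/91 = 5.5e-4.

## Effect-size map comparison

Genetic-risk maps are built by dichotomizing each PRS at its median
(ties to the low group) and computing pooled-SD Cohen's d per region;
case-control maps supply d per region directly (recoverable from a t
statistic as `d = t * sqrt(1/n1 + 1/n2)`). A weighted crosswalk (rows sum
to 1 per target region) converts cluster-parcellation maps into the
34-region bilateral Desikan-Killiany atlas where comparisons run. Median
dichotomization sacrifices power relative to continuous modeling but
makes the genetic-risk contrast commensurable with case-control d values.

Two maps over n shared regions are compared by:

- **Sign concordance**: k = #{regions with d_a * d_b > 0}, one-sided
  exact tail P(X >= k), X ~ Binomial(n, 1/2). Regions with an exactly
  zero d are excluded from n rather than scored half — this keeps the
  test exact; both k/n and the proportion are reported so either
  convention is auditable.
- **Spatial correlation**: Pearson r with the printed interval half-width
  `1.96 * sqrt((1-r^2)/(n-2))`, and a permutation p-value from region-label
  permutations of one map: exhaustive over all n! permutations for
  n <= 8, otherwise 10,000 random permutations (default) with the
  bias-corrected estimate `(count+1)/(n_perm+1)`, giving a p floor of
  1e-4 at the default count. `n_perm = 0` reports the p-value as
  unavailable (NaN), never 0. These label permutations ignore spatial
  autocorrelation; surface-based "spin" nulls are out of scope.
- **FDR**: Benjamini-Hochberg across the disorders within one modality.

## Mendelian randomization

Two-sample summary-data MR between the three global measures and the
disorders, both directions. Harmonization aligns outcome to exposure
effect alleles (allele swaps negate beta, strand flips are complemented),
removes palindromic A/T and C/G variants, and optionally removes SNPs in
supplied long-range-LD regions (BED-like chrom/start/end; applied when
the summary tables carry chr/bp columns). Instruments are exposure
associations with p < 5e-8 by default. Instruments are treated as
mutually independent (identity LD): the package consumes clumped or
simulated variants, and reference-panel LD modeling is out of scope.

Estimators (all authored here; per-SNP ratio `r_j = b_yj / b_xj`):

- **IVW**: weighted regression of b_y on b_x through the origin, weights
  `1/se_y^2`; fixed-effect SE.
- **Egger**: same with a free intercept; the intercept estimates
  directional pleiotropy; residual dispersion floored at 1
  (multiplicative random effects); t-based p with k-2 df.
- **Weighted median**: interpolated weighted median of ratios with
  first-order inverse-variance weights; parametric bootstrap SE
  (1,000 draws, seeded).
- **Weighted mode**: mode of the weighted Gaussian-kernel density of
  ratios, modified-Silverman bandwidth times a user factor (default 1);
  bootstrap SE.
- **GSMR-style**: iterative HEIDI outlier filtering — from the current
  IVW estimate, each SNP's standardized deviation uses the delta-method
  ratio variance `(se_y^2 + r_j^2 se_x^2)/b_x^2`; SNPs with two-sided
  p < 0.01 are removed and the estimate refit until stable. A threshold
  of 0 disables filtering, reducing exactly to IVW. The 0.01 default is
  the GSMR convention.

Sensitivity: Cochran's Q on ratio estimates with delta-method weights
(first-order weights alone are anti-conservative — measured rejection
7.6% vs 2.2% at nominal 5% in the package's own null calibration),
Egger intercept, and leave-one-out IVW with the maximum-deviation SNP
flagged.

The bidirectional scan reports forward (brain -> disorder) cells as odds
ratios `exp(beta)` with 95% CI and reverse cells on the beta scale, with
tiers nominal 0.05, disease-wise 0.05/3 (three global measures), and
study-wise 0.05/39 = 1.3e-3. Missing directions are marked unavailable.

## Quadrant enrichment

PRS and a global measure are standardized over the **full** sample
(cases and non-cases together — standardizing within the healthy
subsample would shift the quadrant boundary; the full-sample convention
is flagged as this package's choice). Diagnosed individuals are
cross-classified by the signs of the two z-scores; ties at exactly 0 go
to the low side (a deterministic rule for a measure-zero event). The
count in the (PRS > 0, brain < 0) quadrant is tested against the 25%
chance rate with the exact one-sided upper binomial tail, per the
directional hypothesis that high genetic liability and smaller brains are
joint risk factors. The test is conservative for small case counts
(discreteness), which the calibration tests confirm.

## Numerical and design notes

- All generators and permutation/bootstrap procedures take explicit
  seeds; a fixed seed reproduces outputs byte-for-byte, and the pipeline
  manifest records every derived seed.
- Simulation sizes in the test suite and acceptance script (cohorts of
  3,000-33,861; 300-500 Monte-Carlo replicates; 50-instrument GWAS pairs
  at n = 100,000) were chosen as the smallest scales at which the
  Monte-Carlo error is comfortably below the tolerances being checked.
- The GWAS simulator draws instrument non-centralities uniformly on
  (7, 12) SD so essentially all true instruments pass the 5e-8 selection
  threshold at the stated sample size; standard errors follow the
  standardized-trait form `1/sqrt(2 f (1-f) N)`.
- Degenerate inputs fail loudly: constant PRS, zero pooled SD, constant
  global measures, rank-deficient covariates, non-PSD correlation
  matrices, empty SNP intersections, all-instrument HEIDI removal.

## Known limitations

- Identity-LD MR: no reference-panel LD, no clumping; supplying
  unclumped summary statistics will overstate instrument independence.
- Label-permutation nulls ignore cortical spatial autocorrelation.
- Synthetic diagnoses are independent across disorders (no comorbidity),
  and the liability model is linear-Gaussian.
- The crosswalk generator produces block-structured synthetic weights;
  real atlas conversions should supply an empirically derived table.
- Published case-control effect-size tables and real GWAS summary data
  are not bundled; analyses of real data require the user to supply them
  in the documented CSV/TSV formats.
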