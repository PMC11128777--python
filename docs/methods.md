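# Methods

## The model

`twinvol` estimates genetic and environmental variance in regional brain
volumes from twin-family data using the classical twin design. The
contrast between monozygotic (MZ) pairs, who share all segregating genes,
and dizygotic (DZ) pairs, who share half on average, identifies three
variance sources per phenotype: additive genetic variance (A), common or
shared environment (C), and a residual unique-environment term (E) that
also absorbs measurement error. Dominance (D) effects are confounded with
C in twin-only designs; a D structure (DZ coefficient 0.25) exists behind
the `use_d` flag for completeness but is never selected by the default
pipelines, so reported A implicitly includes non-additive genetic
variance.

Each family is a block of up to three members (twin1, twin2, one
singleton sibling). The expected within-family covariance per trait is
assembled from the direct variance parameters:

| element                | expectation     |
|------------------------|-----------------|
| member with itself     | A + C + E       |
| MZ co-twins            | A + C           |
| DZ co-twins            | 0.5·A + C       |
| twin–sibling           | 0.5·A + C       |

Full siblings receive the same coefficients as DZ co-twins (0.5 for A,
full C) — the standard classical-twin treatment. Unpaired twins are
retained as size-1 blocks; they inform means and variances but not the
MZ/DZ contrast.

**Direct variance parameterisation.** A, C and E enter the covariance
linearly and are unbounded, so negative variance-component estimates are
possible (and are a legitimate diagnostic of model misfit rather than an
error). Positive definiteness is enforced only softly: any parameter
vector whose implied family covariance fails a Cholesky factorisation
receives a pseudo-infinite objective value. No Cholesky/path-coefficient
parameterisation is used anywhere, including the bivariate models, where
the cross-trait A and E covariances are free parameters.

**Likelihood.** Estimation is full-information maximum likelihood: each
family contributes the multivariate-normal log density of its *observed*
cells under the corresponding row/column subset of its expected mean and
covariance. Families with no observed phenotype contribute zero and are
dropped with a logged count. Missing phenotype cells are never imputed.

**Mean model.** Per-dataset intercepts plus optional age, sex and ICV
regressors (a TCV-in-place-of-ICV mode is a configuration choice at the
pipeline level; in that mode total cerebellar volume is excluded as an
outcome). In the saturated structure the means are free per twin-order ×
zygosity group, plus a sibling mean. Covariate significance is reported,
but covariates are always retained in the variance models.

## Model fitting

The likelihood is *concentrated* over the mean coefficients: for fixed
covariance parameters the optimal coefficients solve a generalised
least-squares system exactly, so the optimizer searches only the variance
parameters. Because the expected covariance is linear in every variance
parameter, the gradient of the concentrated −2lnL is available in closed
form (envelope theorem), and quasi-Newton (L-BFGS) optimisation uses it.
Multi-start: the first start uses moment-based initial values (OLS
residual second moments combined via the twin-covariance algebra); by
default four further starts perturb them by ±20%. Convergence tolerance
is 1e−8 on −2lnL. A non-converged best fit triggers one derivative-free
(Nelder–Mead) refinement; a fit that still fails is returned flagged,
never silently dropped.

Internally every trait is expressed as the residual from a rough OLS fit
(per-dataset intercept + the model covariates) divided by the residual
SD, and covariates are centred/scaled, so optimisation always happens
near unit scale regardless of the mm³/mm⁶ magnitudes; estimates are
transformed back, and −2lnL is always reported on the raw scale (the
change-of-variables term is added), so likelihoods are comparable across
fits with different internal scalings — this is what makes the
covariate-drop LRTs valid.

**Inference.**
- LRT: statistic = Δ(−2lnL), df = difference in free-parameter counts,
  chi-square upper tail. Negative statistics within 1e−4 are clipped to
  zero; anything worse raises (it indicates a failed or non-nested fit).
- AIC = −2lnL + 2k. Sub-model selection is LRT-first: among AE/CE/E
  sub-models not rejected against ACE at the working alpha, the lowest
  AIC wins (ACE itself is always a candidate).
- Profile 95% confidence intervals: a bound b satisfies that the −2lnL
  minimised subject to quantity = b exceeds the unconstrained minimum by
  χ²₁(0.95) = 3.84. The constrained refits use SLSQP with warm starts;
  bounds are bracketed outward from the estimate (initial step 0.02,
  growth 1.6×, cap 0.25) and solved by Brent's method to 1e−4. A bound
  not bracketable within ±2.0 of the estimate is reported one-sided as
  ±inf. A quantity pinned by construction (standardized E in an E-only
  model) collapses to a point interval.

## Pipeline stages

1. **QC** — volumes beyond 3.29 SD (two-sided 0.001 normal quantile) of
   the per-dataset, per-region mean are set missing in a single pass
   (statistics are not recomputed after removals; re-screening is a
   deliberate separate action). SD uses the n−1 denominator. A zero-SD
   region yields zero flags.
2. **Reliability** — ICC(2,1): two-way random effects, single measure,
   absolute agreement, with Shrout–Fleiss F-based 95% intervals;
   subjects missing either visit are dropped pairwise per region.
   Degenerate (zero between-subject variance) data returns a value near
   0 with a warning instead of raising.
3. **Saturated models** — per region and dataset, assumption tests run
   as a sequential nested chain (each step adds one constraint set and
   is compared to the previous step): birth-order means → zygosity-group
   means → twin-vs-sibling means → birth-order variances →
   zygosity-group variances → twin-vs-sibling variances. Because
   zygosity groups are sex-specific, a sex regressor is exactly
   collinear with the free group means; the saturated means model
   therefore carries age/ICV only, and all three covariate LRTs (age,
   sex, ICV; df = 1 each) run against the order/zygosity-equated
   correlation model, where sex is identified. Twin correlations rMZ and
   rDZ are maximum-likelihood correlations from that constrained model
   (variances and covariances equated within zygosity class), which lets
   unpaired twins contribute.
4. **Univariate decomposition** — per region: dataset-specific ACE;
   ACE with variance components equated across datasets (means stay
   dataset-specific); equating LRT (df = 3 per additional dataset);
   AE/CE/E sub-models and selection as above; standardized components
   with profile CIs. If equating is rejected, the row is flagged and
   per-dataset estimates are reported alongside. The pipeline defaults
   to uniform selection (the majority model across regions) with the
   per-region choice retained in the output. Two dataset-specific
   estimates can be pooled by fixed-effect inverse-variance
   meta-analysis (SE = CI width / 3.92).
5. **Bivariate decomposition** — pairwise bivariate AE fits over all
   region pairs (pooled-dataset mode by default): per-trait A and E plus
   free cross-trait A and E covariances. Reported quantities:
   r_A = cov_A/√(A₁A₂), r_E likewise, model-implied r_ph, and the
   contributions r_ph_a = √h₁²·r_A·√h₂² and r_ph_e analogously. r_ph_a
   is computed as cov_A/√(V₁V₂) — algebraically identical when both A
   estimates are positive but still defined when a direct-parameter A
   estimate is negative (r_A itself is then reported as NaN with a
   note). Under the AE model r_ph_a + r_ph_e = r_ph exactly.
   Significance: refit with the genetic (df 1), environmental (df 1) or
   both (df 2, phenotypic) covariances fixed at zero, then LRT. The m
   measures populate m×m symmetric matrices; the phenotypic matrix has
   unit diagonal, the contribution matrices leave the diagonal
   undefined.
6. **Multiple testing** — Benjamini–Hochberg step-up FDR control applied
   separately within exactly four families: covariate effects,
   assumption tests, univariate model fits, bivariate covariances.
   Family membership is attached when a test is created, so no p-value
   can ever be corrected in two families.

## Synthetic cohorts

The generator draws family blocks under the exact latent model above:
A factors correlate 1.0 between MZ co-twins and 0.5 between DZ co-twins
and twin–sibling pairs; C is shared with correlation 1.0 within family;
E is independent. Cross-region structure follows user-supplied genetic
(R_A) and environmental (R_E) correlation matrices (validated symmetric
PSD with unit diagonal before any sampling). The C-factor cross-region
matrix defaults to identity — the stated worlds carry C variance of zero,
so nothing downstream depends on it. Everything is deterministic given
the seed, which is echoed into the cohort metadata.

The default two-dataset world mirrors the composition of two Queensland
twin cohorts: QTIM — 115 MZ, 110 same-sex DZ and 56 opposite-sex DZ
pairs, 200 unpaired twins, 36 sibling-augmented families, 798
individuals, ages ≈ 22.1 ± 4.3 (range 12–30); QTAB — 93 MZ, 62 same-sex
DZ and 31 opposite-sex DZ pairs, 24 unpaired twins, 396 individuals,
ages ≈ 11.3 ± 1.4 (range 9–14). The opposite-sex share of DZ pairs and
the sex split of same-sex pairs are not published at that granularity
and are set to roughly a third of DZ pairs and an even split
respectively. The 29 measures (28 cerebellar regions + total) carry
AE-structure heritabilities between 0.47 and 0.91, matching the span
reported for such volumes; homologous left/right pairs share R_A = 0.8
and R_E = 0.3. Region mean volumes are plausible synthetic magnitudes
for an ACAPULCO-style parcellation (the source tables are not public at
that granularity); the ACE variance defaults to a 10% coefficient of
variation around the mean. ICV scales regions proportionally
(≈40% of raw variance), males run ≈2% larger at fixed ICV, and age
effects default to zero (the adolescent/adult age effects reported for
these volumes are sparse and small). ICV itself carries a 50% family-
shared variance component, which is what makes the "omitting ICV
inflates C" property testable. Missingness is missing-at-random uniform
over cells (default 1%), emulating QC-driven exclusions without
modelling their mechanism.

Retest tables: the observed value is the test visit; the retest visit is
mean + ρ(y − mean) + √(V(1−ρ²))·z with dataset moments (mean, V), so the
population ICC(2,1) equals ρ and ρ = 1 reproduces the test exactly. The
default subsample size is 43, with rescan intervals ≈ 113 ± 56 days.
Outlier injection displaces selected cells outward to exactly
`magnitude_sd` clean-group SDs from the clean mean; magnitudes ≤ 3.29
are rejected because such cells would be undetectable by design, and
positions are logged for recall tests.

**What a green test does not establish.** The generator is the model:
multivariate-normal phenotypes, exactly linear covariate effects, MAR
missingness, no segmentation error, no dataset differences in
covariance structure beyond those injected. Recovery and calibration on
these cohorts validate the estimation machinery, not the biological
conclusions of any particular empirical dataset; real parcellation data
add non-normality, QC-informative missingness and acquisition
differences that these tests do not probe.

## Numerical choices and limitations

- Optimizer tolerance 1e−8 on −2lnL; profile-CI bisection tolerance
  1e−4; LRT negative-statistic clip 1e−4; decomposition identity holds
  to ~1e−10 in practice.
- Saturated-model initial values are per-group ML moments, which are the
  exact MLE for complete data without covariates — the optimizer then
  simply verifies stationarity, which is why moment-recovery holds to
  1e−6.
- The equating LRT compares parameter counts across two
  parameterisations of the same family (dataset-specific vs shared
  variance components); nesting holds because the shared model is the
  equal-components subspace.
- At most one singleton sibling per family; larger sibships raise a
  validation error rather than silently extending the covariance
  structure.
- Sex-limitation models (sex-specific variance components for
  opposite-sex pairs) are out of scope; the sex covariate alone carries
  sex differences in means.
- Model selection happens per region at the working alpha; the FDR
  adjustment is merged into the reports afterwards. With selection
  contingent on multiple tests, the reported CIs for the selected model
  are conditional on selection, as is standard in this literature.
- Pairwise bivariate fits do not constrain the 29-variate system to be
  jointly positive definite; the assembled matrices are therefore not
  guaranteed PSD (the pairwise estimates are what the matrices report).
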