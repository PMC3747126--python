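# Methods

`sibewas` implements an epigenome-wide association analysis of serum
C-reactive protein (CRP) on Infinium-style methylation arrays, for cohorts
with sibship structure.  This note records the statistical model, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the open design decisions we resolved.

## Pipeline overview

1. **Sample QC.** Each array carries 56 control probes measuring assay
   steps (staining, hybridization, target removal, extension, bisulfite
   conversion, mismatch, negative controls).  A sample is excluded when any
   control feature deviates more than `k_sd` (default 4) standard
   deviations from that feature's cross-sample mean.  Zero-variance
   features cannot flag anyone.  At the default threshold, roughly
   `2 * Phi(-4) = 6e-5` of clean sample-feature pairs exceed the cut by
   chance, so a handful of false exclusions per ~50,000 comparisons is
   expected and harmless; genuinely degraded samples sit far outside the
   cut and are caught with certainty (the displacement has to shrink to
   near 4 SD before recall suffers).

2. **Site QC.** Sites on chromosomes X and Y are removed.  Each remaining
   probe's methylated and unmethylated cross-sample intensity vectors are
   tested for multimodality with the Hartigan dip test (below); a probe is
   set aside when either channel rejects unimodality at p < 0.001.
   Cross-reactive probes and probes overlapping known SNPs are *flagged
   and reported separately* rather than dropped: they are tested like any
   other probe so their results can be inspected, but a strict mode
   (`drop_flagged`) removes them up front.  The dip test runs on
   post-sample-QC, pre-normalization intensities; this is configurable,
   and we chose the raw scale because multimodality caused by genotype or
   cross-hybridization is a property of the raw signal that normalization
   should not be allowed to mask.

3. **Normalization.** Chip and batch effects hit target and control probes
   alike.  The 56 control features are standardized and decomposed into
   principal components across samples; the number of components defaults
   to the Kaiser rule (eigenvalue > 1 on standardized features), which on
   our synthetic data selects exactly the planted chip direction.  For each
   probe and channel independently, `log(intensity + 1)` is regressed
   across samples on the control scores; the normalized intensity is
   `exp(intercept + residual) - 1`, floored at zero.  Working on the log
   scale matches a multiplicative chip-effect model; re-adding the
   intercept keeps intensities on their original scale so beta-values stay
   interpretable.  The operation is idempotent and leaves residuals
   numerically orthogonal to every control score.

4. **Beta-values.** `beta = M / (M + U + alpha)` with the platform
   convention `alpha = 100`.  The offset stabilises low-intensity probes at
   the cost of a ~`alpha / (M + U + alpha)` multiplicative shrinkage, about
   1-2% at typical intensities.

5. **Association.** Per site, the model is

       lnCRP_ij = b0 + bx * beta_ij + g' c_ij + u_i + e_ij

   with covariates `c` (age, sex, BMI, current smoking by default;
   hypertension for the sensitivity model; methylome PCs when requested),
   a sibship random intercept `u_i ~ N(0, s_sib^2)` and residual
   `e_ij ~ N(0, s_res^2)`.  CRP is analysed on the natural-log scale
   because of its right skew.  Estimation is restricted maximum likelihood
   profiled to the single variance ratio `theta = s_sib^2 / s_res^2`: for a
   random-intercept model the covariance inverse has a closed per-sibship
   Woodbury form, so one likelihood evaluation is O(n) and a full scan of
   thousands of sites takes seconds on one core (estimates agree with
   lme4/statsmodels REML to at least five digits; the test suite asserts
   this).  Inference on `bx` is a two-sided Wald z-test.  When every
   sibship is a singleton the model is unidentified and reduces exactly to
   OLS, which is then used directly (t-based p-values); the same fallback
   applies when the variance ratio collapses to zero or the optimizer
   fails, with the fit flagged through the reported variance components.
   The exposure stays on the natural 0-1 beta scale (no M-values), so
   coefficients read as change in lnCRP per unit methylation.
   Sex-by-methylation interactions are Wald tests on the product term in
   the same mixed model, run on a supplied probe subset (the significant
   sites), with the random effect retained.

6. **Multiple testing and inflation.** Bonferroni thresholds are
   `alpha / m`; false-discovery q-values use Benjamini-Hochberg step-up
   (`q_(i) = min_{j>=i} p_(j) m / j`).  The genomic inflation factor is the
   median of the per-site 1-df chi-square statistics over the null median
   0.4549.  QQ coordinates pair uniform order statistics `i/(m+1)` with
   sorted observed p-values on the -log10 scale.  To absorb unmeasured
   global confounders, the top k (default 3) principal components of the
   probe-standardized beta matrix can be appended to the covariates; on
   synthetic data with a planted global confounder this restores lambda
   from >1.1 to 1 +/- 0.05.

7. **Internal replication.** Sibships are split into two mutually
   unrelated subsets: one randomly chosen member of every sibship of two
   or more goes to subset 1 and a second, distinct member to subset 2
   (members beyond the second stay unused); singletons are divided evenly
   at random, with an odd one dropped so the subsets stay the same size.
   Top hits are re-tested per subset with ordinary least squares (no
   random effect is needed among unrelated individuals) at the per-test
   threshold `alpha / k`; verdicts are both / one / neither plus
   coefficient-sign concordance.

8. **Enrichment.** Significant probes map to gene symbols via the
   manifest; each term of a user-supplied annotation file (two-column TSV
   or GMT) is tested with a one-sided hypergeometric upper tail.  The
   background defaults to all genes on the tested array rather than the
   genome: the array's gene universe is the sampling frame from which
   significant genes were drawn.  Raw p-values are reported alongside BH
   q-values across terms.

## The dip test

The dip of a sample is the smallest sup-norm distance between its
empirical CDF and any unimodal CDF (convex, then concave, with an atom
permitted at the mode).  We implement the classical O(n) algorithm that
maintains a candidate modal interval and greatest-convex-minorant /
least-concave-majorant fits.  The implementation is verified in the test
suite against an independent brute-force oracle that minimizes the
distance by linear programming over unimodal CDFs, mode by mode.
Significance comes from Monte-Carlo calibration against uniform samples —
the unimodal null with the stochastically largest dip — with add-one
smoothing `p = (b + 1) / (n_boot + 1)`; the default `n_boot = 2000` makes
the smallest attainable p-value 1/2001, just below the 0.001 screening
cut.  The uniform null is conservative for any other unimodal law, so the
realized false-flag rate on, say, Gaussian-shaped probes is far below the
nominal level; the null table is cached per sample size, so a scan pays
the simulation cost once.

## Synthetic data

The generator builds a full study: cohort with sibship structure,
phenotypes, a latent beta matrix, intensities, control probes, a manifest,
and sidecar ground truth (planted effect sites, planted bimodal sites,
planted bad samples, sibship intercepts, chip assignment).

* **Design.** 492 sibships by default, sizes 1-10 drawn from a 40.2%
  singleton + truncated-geometric distribution calibrated to a mean of
  1.96 members; samples are laid onto 12-sample chips.
* **Phenotypes.** 70.9% female; age 66.1 +/- 7.6 (F) and 66.7 +/- 7.6 (M);
  BMI 32.1 +/- 6.6 (F) and 29.0 +/- 4.8 (M); 83.5% / 80.1% hypertensive.
  The current-smoker fraction defaults to 10%, a realistic rate for a
  hypertension-enriched cohort in its mid-sixties (the emulated design
  does not pin this number down).
* **CRP.** Simulated on the ln scale: sex-specific intercepts equal to the
  log medians 0.38 (F) and 0.27 (M) mg/L, small centred age/BMI/smoking
  effects, a sibship random intercept (SD 0.45) and residual (SD 1.0),
  giving a total ln-scale SD near the 1.1 implied by the reported
  quartiles.  Planted methylation effects enter centred so the intercepts
  keep setting the medians.
* **Methylation.** Probe mean beta-values are bimodal *across* probes
  (island-like low, body-like high) but each probe is unimodal across
  samples: within-probe variation is log-normal on the logit scale,
  targeting a beta-scale SD of 0.08 mid-range and shrinking toward the
  boundaries — variance proportional to m(1-m), as on real arrays, and no
  boundary atoms that would fool the dip test.  Planted-effect probes get
  mid-range means (0.25-0.75): variably methylated sites are the ones an
  EWAS can discover.  Planted bimodal probes mix two logit-normal
  components centred at beta 0.25 and 0.75.
* **Intensities.** `M = T * beta`, `U = T * (1 - beta)` with probe-level
  log-normal totals around 4000, an additive per-chip log-scale effect
  (SD 0.15) shared by both channels and by the control probes, a
  per-observation brightness term (log SD 0.12) also shared by both
  channels, and small channel-specific noise (log SD 0.03).  Because chip
  and brightness terms are common to M and U they cancel in the
  beta-value; only the channel noise (~0.01 beta units, the scale of
  technical replicates on this class of array) blurs methylation, so
  planted coefficients survive the pipeline essentially unattenuated.
* **Planted structure.** Bad samples have a third of their control
  features displaced 6 SD (configurable); planted association effects are
  specified as (probe index, lnCRP per unit beta) pairs, typically -3 to
  -4 to match the coefficient scale of genuine hits at this design size.

What the generator does **not** emulate: dye chemistry and probe-type
biases, genotype-driven methylation (meQTLs), cell-type composition
heterogeneity, age-related global drift, missing data, or any correlation
between neighbouring probes.  Passing tests therefore demonstrate that the
statistical machinery is correct and well calibrated under the stated
model, not that the pipeline is robust to every artefact of real arrays.

## Problem sizes used in tests

The test suite exercises the pipeline at a deliberately reduced scale
chosen to keep the whole suite fast while leaving every statistical check
well powered: cohorts of ~950-970 samples (the emulated design size),
probe panels of 300-1200 instead of ~27,000, 200 replicates for bias
checks, 1000 null sites for type-I calibration, and 2000 bootstrap
samples for dip-test p-values.  All of these appear as explicit
parameters, so scaling up is a configuration change, not a code change.

## Known limitations

* The mixed model fits a single random intercept per sibship; kinship
  matrices, twins, or half-sib structure are out of scope.
* The dip-test null table is simulated per sample size; scans over cohorts
  with per-probe missingness (varying n) would lose the caching benefit.
* BH q-values assume independence-ish behaviour (PRDS); no
  Benjamini-Yekutieli option is exposed.
* The enrichment test treats gene sets as flat; term hierarchy and
  redundancy handling of dedicated GO tools is not emulated.
* With fewer than ~100 tested sites the inflation factor is unstable and
  the CLI skips it.
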