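# Methods

## Overview

`scnpipe` implements an analysis chain linking neonatal brain structure and
the home environment to childhood outcomes in very-preterm cohorts:

1. **Morphometry preprocessing** — per-subject log-Jacobian determinant maps
   (voxelwise log expansion/contraction relative to a group template, affine
   head-size component removed) are Gaussian-smoothed in the log domain,
   resampled to the analysis resolution, masked to tissue of interest, and
   stacked into a voxels × subjects matrix. Voxel values are exponentiated
   before factorization so the input is strictly positive.
2. **Structural covariance networks (SCNs)** — non-negative matrix
   factorization X ≈ W·H decomposes the matrix into spatial networks
   (columns of W) and subject expressions (rows of H). The rank k is chosen
   by split-half stability. Each subject's *network volume* is the weighted
   mean log-Jacobian, value[n, j] = Σ_v W[v,j]·logJ[v,n] / Σ_v W[v,j],
   computed in the log domain.
3. **Outcome components** — a 32-measure behavioral/cognitive battery is
   reduced by PCA on the correlation scale after age residualization of
   measures that are not age-normed. Components are retained when
   significant under a column-permutation test and reliable under repeated
   split-half analysis.
4. **Association models** — for each network (and for the cognitively
   stimulating parenting score) a multivariate linear model tests the effect
   on all retained components simultaneously via Pillai's trace, controlling
   for gestational age (GA), postmenstrual age at scan (PMA), sex and the
   deprivation index (IMD; parenting models omit PMA). Omnibus tests are
   Bonferroni-corrected across networks; significant omnibus effects get
   per-component follow-up regressions corrected across components. A
   combined additive model enters network volume and parenting together, and
   nested-model F tests probe a parenting × volume interaction. A
   sensitivity suite reruns the primary models under twin removal, ±3 SD
   outlier exclusion, lesion-grade adjustment, and maternal
   education/age covariates.
5. **Synthetic cohort generator** — produces cohorts with the full
   statistical structure above plus known ground truth, so every stage is
   validated by parameter recovery.

## Factorization

Frobenius-loss multiplicative updates with NNDSVDa initialization (SVD-based,
negative parts folded, zeros replaced by the matrix mean, tiny seeded jitter
to break symmetric ties). The per-iteration loss is computed through the
trace identity ‖X−WH‖² = ‖X‖² − 2 tr(HᵀWᵀX) + tr(WᵀW·HHᵀ), which avoids
forming the V × N residual; below 1e-14·‖X‖² the identity is dominated by
cancellation error and the loss is reported as zero. Iteration stops when
the relative loss decrease falls below `tol` (default 1e-5–1e-7 depending on
stage) or at `max_iter`. Multiplicative updates guarantee a non-increasing
loss, which the tests verify to 1e-10 relative tolerance. A random
initialization is available (`init="random"`); all fits are deterministic
given the seed.

## Rank selection

For each candidate rank, subjects are split at random into halves
`n_splits` times (default 8–10); the factorization is fitted in each half and
networks are matched across halves by exact linear-assignment. Two design
choices depart from the most obvious construction, both for measurable
reasons:

* **Stability metric: Pearson correlation of matched maps, not raw cosine.**
  Non-negative spatial maps share a large positive baseline, so raw cosine
  similarity between half-sample solutions stays at ~0.8+ at every
  over-factorized rank and the stability curve carries almost no
  information. Centering (Pearson) removes the shared baseline; on planted
  data the true rank then reads ~0.95 while neighboring ranks sit at ≤0.85.
* **Selection rule: largest rank at a local maximum of the stability curve
  that clears the threshold (default 0.875).** Very low ranks are
  generically stable (gross merges are trivially reproducible) and
  over-factorized ranks decay slowly, so "largest rank above threshold"
  chases plateaus; a reproducible decomposition instead announces itself as
  the last peak above the reliability bar. With no qualifying rank the
  report is flagged (`no_stable_rank`) and the smallest candidate returned
  with a warning.

Reconstruction error per rank is reported as a non-decisive elbow
diagnostic. Both the metric and the rule are arguments (`metric="cosine"`,
`rule="largest"` restore the plain construction).

## Outcome component retention

* Non-age-normed measures are residualized on (GA-corrected) age at
  assessment with a straight-line fit; age-normed measures (the intelligence
  subscales) skip this. All measures are then standardized (sample SD), so
  the PCA operates on the correlation matrix.
* Missing data: subjects missing >20% of measures are excluded; remaining
  gaps are median-imputed before standardization.
* Sign convention: within each component the largest-|loading| entry is made
  positive, making outputs reproducible across runs and platforms.
* **Permutation test** (parallel-analysis style): each measure is permuted
  independently across subjects; the p-value for component c compares its
  observed variance-explained share with the null distribution of the
  c-th share, with the add-one estimator (1+exceedances)/(1+n_perm).
* **Split-half reliability**: per random split, PCA is refitted in each
  half; components are matched across halves by maximal absolute loading
  correlation (exact assignment; absolute values absorb sign indeterminacy)
  and component c's reliability is its mean matched |r|.
* **Retention rule**: a component is kept iff permutation p < α (default
  .05) and reliability ≥ r_min (default 0.70), and the retained set is
  forced to be a prefix of the component order — a later component is never
  kept past a failing earlier one, since later components explain less
  variance and are not interpretable as standalone outcome dimensions when
  an earlier dimension already failed. Both thresholds are configuration
  parameters, and the report always lists significance and reliability
  separately so a borderline third component is visible rather than
  silently dropped.

## Association statistics

The omnibus statistic is Pillai's trace V = tr(H(H+E)⁻¹) computed from the
hypothesis and error SSCP matrices of the multivariate linear model, with
the conventional F approximation; for a single-df predictor all four
classical statistics coincide, and with one outcome the test reduces exactly
to the univariate partial F. Wilks' lambda is available via
`statistic="wilks"`. The implementation is validated in the tests against a
from-scratch SSCP/eigenvalue computation and against `statsmodels` MANOVA.

Follow-up regressions are ordinary least squares (via statsmodels) with
Bonferroni adjustment p·m capped at 1. The Bonferroni threshold helper
reports both full precision and the 3-decimal display form (α=.05 over 15
models → .003). The interaction test is the extra-sum-of-squares F between
nested models, exact under Gaussian errors (a likelihood-ratio test in F
form); the interaction column is the product of mean-centered predictors.

Listwise deletion is applied per model and the analyzed n is always
recorded. Covariates that are constant within an analysis sample (e.g.
lesion grade in a sample where nobody has lesions) are dropped with a
warning rather than producing a singular design; this also makes such
sensitivity variants exact no-ops, which the tests exploit. The outlier
screen uses mean ± 3 SD computed once on the analysis sample, one pass.
Sex is coded 0/1; lesion grade 0 = none, 1 = minor (major lesions are
excluded upstream of imaging analyses); maternal education is an ordered
numeric with three levels.

## Synthetic cohort generator

The generator emulates the *statistical* structure the chain assumes, not
anatomy. What it does and does not capture determines what passing tests
mean: they demonstrate correctness and calibration of the pipeline under
its own model assumptions, not performance on real morphometry (no
registration artifacts, no spatially correlated noise, no lesion effects,
no missing visits).

* **Covariates** match the cohort demographics the analysis expects: GA at
  birth from a left-skewed scaled Beta(3.2, 1.45) on [23.57, 32.86] weeks
  (median ≈ 30.3); PMA at scan truncated normal, center 42.57 in
  [37.86, 44.86] (hence GA < PMA always); sex Bernoulli(0.508); IMD
  N(20.02, 11.82²) truncated at 0; parenting N(17.68, 2.43²); maternal age
  N(32.84, 5.70²); maternal education ordinal (10.2/15.9/73.9%); minor
  lesions 56.8%; 10% of subjects paired into twin groups.
* **Networks** are smoothed ellipsoidal blobs, one per cell of a jittered
  lattice so supports are disjoint for any seed (pairwise cosine < 0.2 by
  construction, support ≥ 50 voxels), truncated at 20% of peak and
  flattened (shape exponent 0.05) into plateaus with soft edges,
  peak-normalized. The plateau shape keeps the downstream exponentiation
  nearly rank-preserving within each support, which is what makes
  factorization-based recovery well-posed. Default grid 20×24×20 at 2 mm
  (a desk-scale stand-in for an atlas grid; all sizes configurable).
* **Mask** = union of network supports (dilated by one voxel), emulating a
  tissue atlas mask. A large signal-free background would contribute a
  constant exponentiated baseline (exp(0) = 1) that the factorization
  splits arbitrarily across components, destabilizing rank selection — an
  artifact a tissue-restricted mask avoids, exactly as a gray-matter atlas
  does for real maps.
* **Subject loadings** are truncated lognormal: log H = 0.6 + dev with
  dev ~ N(0, 0.4²) clipped at ±1.1. The truncation bounds the exponentiated
  dynamic range; an unbounded tail occasionally lets a single
  subject-network block dominate the Frobenius loss and derail the fit.
  The designated network's deviation additionally carries 0.35·g for a
  standard-normal latent cognitive driver g, giving corr(true volume,
  driver) ≈ 0.6.
* **Maps**: logJ_n = Σ_j W_j·H[j,n] + N(0, 0.05²) voxel noise. The signal
  amplitudes are synthetic-scale (larger than physiological log-Jacobians)
  so that desk-scale grids retain the signal-to-baseline contrast a
  37k-voxel atlas analysis gets from its sheer voxel count.
* **Battery**: three latent factors — "preterm phenotype" (symptom scales
  load +0.8, intelligence general/nonverbal −0.3), "cognitive"
  (intelligence subscales +0.75–0.8), "socioemotional"
  (temperament/empathy +0.7) — plus N(0, 0.7²) measurement noise, chosen so
  the top three components explain ≈ 58–60% of variance. Non-age-normed
  measures receive a linear age drift (0.3 SD per SD of age) that the
  preprocessing must remove.
* **Planted effects**, standardized scale: parenting → phenotype factor
  β = −0.40; designated network volume → cognitive factor β = +0.40. The
  study-reported raw-scale coefficients translate to partial correlations
  of roughly 0.2–0.27 at the study's sample sizes, which would put
  corrected-threshold detection near 50–60% power at N = 200; the defaults
  are set at the smallest couplings that make parameter recovery a sharp
  test (≥ 80% joint detection) rather than a coin flip. Raw-scale
  coefficients are recoverable by multiplying by SD(component)/SD(predictor).
* Determinism: all draws descend from one seed via `SeedSequence` spawning;
  identical seeds give byte-identical cohorts.

## Numerical choices and degenerate inputs

* Voxel scan order is fixed (C order, last axis fastest), so W rows and
  scatter-backs are reproducible.
* Smoothing uses reflect padding (avoids edge attenuation); σ per axis =
  FWHM/(2√(2 ln 2))/spacing. Downsampling is trilinear for intensities,
  nearest-neighbour for label masks; upsampling requests are errors.
* NaN/Inf voxels, 4D volumes, grid mismatches, duplicate subject ids,
  non-positive factorization input, all-zero network columns, constant
  thresholding columns, constant predictors and rank-deficient designs are
  rejected with specific errors rather than propagated.
* The weighted network volume divides by ΣW (true weighted mean); dividing
  by V instead (a plain average of the weighted map) is available via
  `normalize="voxels"`.
* Add-one permutation p-values are never 0; `n_perm` must resolve the
  requested α.

## Problem sizes

Default validation sizes: N = 200 subjects, k_true = 6 networks on a
20×24×20 grid (≈ 1.7k in-mask voxels), M = 32 measures, 500–1000
permutations, 8–20 split halves, 50–500 replicates depending on the
quantity. These sizes put every stage's sampling error well below the
margins being tested while keeping the full suite and the acceptance script
in the minutes range on one core.

## Known limitations

* Recovery quality depends on the mask being tissue-restricted; with a
  large empty background the factorization spends components on the
  exponentiation baseline (see Mask above).
* The generator's networks are disjoint; the pipeline does not guarantee
  recovery of strongly overlapping networks, and the rank-selection rule
  has only been characterized for near-disjoint planted structure.
* The orthogonality-regularized factorization variant cited in parts of the
  SCN literature is not implemented; plain Frobenius NNMF with NNDSVDa
  initialization is the single fitting route.
* Twin clustering is handled by removal (sensitivity variant), not by
  mixed-effects modelling.
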