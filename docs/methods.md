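# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic cohort does and does not
emulate, and the design decisions taken where the workflow left genuine
freedom.

## Synthetic cohort generator

The generator stands in for a retrospective two-center cohort of
anti-VEGF-treated DME eyes. Each synthetic eye consists of a 128×128
8-bit B-scan-like image with a horizontal "inner retina" band mask
(≥10% of pixels; position and thickness jittered per eye), a latent
phenotype class, clinical covariates, and two binary outcomes.

**Texture model.** The band carries a smooth layered reflectivity
profile (two sinusoidal components around a class-specific base level),
a Gaussian-smoothed disruption field whose amplitude is a class
parameter, dark elliptical *cysts* (Poisson-count at a class-specific
density per 1000 masked px², radii drawn from a class range, intensity
×0.25), bright 3×3 *hyperreflective foci*, and additive pixel noise.
The motifs were chosen so that the texture families the analysis leans
on are discriminative: cysts drive gray-level dependence and size-zone
statistics, foci drive high-gray-level emphases and NGTDM busyness, and
the layer profile drives wavelet first-order statistics. Intensities
are generated in [0, 1] and quantized to 8-bit on output; **all feature
math operates on the quantized values**, mirroring the JPG-era inputs
of clinical archives.

**Defaults as study conditions.** The default configuration is 234 eyes
in four phenotypes at proportions (0.52, 0.19, 0.14, 0.15) with
outcome-link probabilities RDME = (0.59, 0.69, 0.59, 0.34) and poor
vision = (0.57, 0.60, 0.66, 0.29) — the cluster structure of the
reference cohort. Class counts come from largest-remainder
apportionment, so equal proportions with divisible n are exactly
balanced. Baseline CMT is lognormal around class medians
(420/510/540/300 µm); post-treatment CMT is synthesized on the correct
side of the band-wise reduction threshold so that re-deriving the RDME
label from the CMT pair reproduces the drawn label exactly (round-trip
invariant). Two presets bracket difficulty: `high_separation_config`
(planted clusters recoverable at ARI ≥ 0.95) and `null_config`
(identical class parameters; recovery should sit at chance).

**What is not emulated** — and hence what passing tests do not show
about real data: optical speckle and device point-spread functions, 3D
volume context, inter-device intensity shifts, patient-level
correlation between fellow eyes (eyes are sampled independently), and
any causal pathway from texture to outcome beyond the class-conditional
Bernoulli link. Covariates are matched in location only, not full
shape.

## Feature extraction

* **Discretization**: fixed bin width, default 25 on 8-bit intensities
  (`level = ⌊(x − min)/w⌋ + 1`), applied per derived image. LBP code
  images are discretized at width 1 since their values are small
  integer labels (codes 0..9); width 25 would collapse them to one
  level.
* **Filters**: single-level separable 2D DWT (Coiflet-1 default),
  subbands nearest-neighbour upsampled and cropped; Laplacian of
  Gaussian at σ ∈ {3, 5} mm converted to pixels by the spacing
  (sub-pixel σ clamped to 1 px with a warning; kernel truncated at 4σ);
  sign-preserving rescaled logarithm/exponential/square/square-root
  point maps; spacing-aware gradient magnitude; rotation-invariant
  uniform LBP (radius 1, 8 points). Derived-image names keep
  engine-style tokens (e.g. `log-sigma-3-0-mm-3D`) for continuity with
  published feature names even though all computation is 2D — single
  B-scans cannot support 3D kernels.
* **Texture matrices**: GLCM at distance 1 over the 4 unique 2D
  directions, symmetric, per-direction normalization, features averaged
  over directions; GLRLM over the same 4 directions (standard
  16-feature set); GLSZM/GLDM with 8-connectivity; GLDM dependence =
  1 + number of in-mask 8-neighbors within the level tolerance α
  (default 0) — including the center keeps the 1/j² emphasis features
  defined for isolated pixels; NGTDM excludes pixels with no in-mask
  neighbor from both the counts and the totals.
* **Degenerate ROIs**: on a constant region, skewness/kurtosis are 0,
  GLCM correlation-type features 1, NGTDM coarseness 1e6, busyness and
  strength 0 — documented constants instead of NaN so downstream
  z-scoring is not poisoned. Masks need ≥16 foreground pixels for
  extraction; smaller masks remain representable (polygon annotations).
* **Shape**: mesh surface from the half-level marching-squares contour
  (shoelace); perimeter by the 4-direction Crofton formula, which is
  directionally unbiased for smooth boundaries (the marching-squares
  polyline overstates a disk's perimeter by ~7%, dragging a disk's
  sphericity to 0.93 instead of ~1); axis lengths from 4·√eigenvalues
  of the physical pixel-coordinate covariance.

The oracle suite re-derives every matrix feature by exhaustive
enumeration (explicit pair walks, run walks, flood fill, neighbor
loops) and requires agreement to 1e−9 relative tolerance on random
small ROIs.

## Dimensionality reduction

Columns are z-scored with the sample SD; zero-variance columns are
dropped with a logged list. PCA is the eigendecomposition of the sample
(n−1) covariance; component signs are fixed (largest-magnitude loading
positive) for bit-reproducibility. Horn's parallel analysis permutes
each column independently (preserving marginals exactly, destroying
correlation; a Gaussian-noise null is available), compares observed
eigenvalues with the 95th percentile of the null per component index,
and retains the leading consecutive components passing the test — the
standard Horn convention. The bootstrap replication stage accepts a
fixed component count (`n_pcs_boot`, conventionally 16) or defaults to
the parallel-analysis result.

## Clustering and k selection

* **Elbow**: k at the maximum second forward difference of **log** WSS
  over k = 2..k_max−1, ties to the smallest k with a low-confidence
  flag. The log scale matters: on raw WSS the first split always
  removes the most variance, so the raw second difference fires at k=2
  even for textbook four-cluster data (0/20 correct in simulation,
  versus 20/20 on the log scale).
* **Consensus**: Monti-style — 100 subsamples of 80% of eyes, K-means
  per subsample, co-assignment frequencies among co-sampled pairs.
  A(k) is the area under the empirical CDF of off-diagonal consensus
  entries (computed as 1 − mean, which is the exact CDF integral);
  Δ(k) = (A(k) − A(k−1))/A(k−1) with Δ(k_min) = A(k_min). The chosen k
  is the **largest k with Δ(k) ≥ 0.1** — the last k that still buys a
  substantial consensus gain before the curve levels off. A
  maximum-drop rule (argmax of Δ(k) − Δ(k+1)) was tried and fires one k
  early whenever the consensus gain is spread over several k.
* **Hybrid**: Ward labels at k supply centroids that initialize a
  single K-means run; the converged K-means labels are final, and
  agreement with pure Ward is reported as an ARI. Labels are
  renumbered 1..k by decreasing cluster size.

## Stability validation

Bootstrap replicates resample eyes with replacement and refit
z-score → PCA → K-means from scratch (not a projection onto the
original loadings); the ARI compares replicate labels with the original
partition restricted to the resampled eyes, duplicates counted with
multiplicity (a unique-instances mode exists). ARI uses the
contingency-table closed form; no label matching is needed since ARI is
permutation-invariant. Replicates with fewer than k distinct rows are
skipped and logged. Noise injection defaults to the image domain (σ on
the [0, 1] intensity scale, features re-extracted); a feature-domain
mode (σ in z-units) is provided because re-extraction is costly, and
output metadata names the domain since the two σ scales are not
comparable.

## Selection cascade

Stage 1 resolves the highest-|r| offending pair first and drops the
member with the larger mean absolute correlation to all other retained
features (ties to the later column) until no retained pair exceeds the
threshold — deterministic and row-order invariant. Stage 2 is a one-way
fixed-effects F-test per feature across cluster labels at raw P < 0.05
by default, with an optional Benjamini–Hochberg mode. Stage 3 follows
the canonical Boruta loop: per iteration, every undecided feature gets
an independently permuted shadow copy; a random forest (impurity
importance) is fit on real + shadow columns; a feature scores a hit
when it beats the best shadow; two-sided binomial tests at α = 0.05,
Bonferroni-corrected across currently undecided features (tested from
iteration 5), confirm or reject; leftovers are tentative. A known
consequence of impurity importance is that a fixed null table's most
chance-correlated column can be legitimately confirmed (its in-sample
correlation is real; shadows are re-permuted each round) — a handful
per hundred null features. Trees default to 500; desk-scale runs use
100–150, which does not change decisions in our simulations, only
their latency.

## Outcome models

Logistic fits are maximum-likelihood (statsmodels) with Wald standard
errors; OR = exp(β) and 95% CI = exp(β ± 1.96·SE) by construction.
Perfect separation is detected (non-convergence or |β| > 20 or SE > 50)
and flagged with an infinite-OR sentinel rather than a spurious
estimate. Backward stepwise starts from univariate entrants (P < 0.1)
and repeatedly removes the largest-Wald-P term ≥ 0.05; an AIC-based
criterion was considered and rejected to keep the final model's
per-term guarantee (all retained P < stay_p). The cluster table uses
Kruskal–Wallis with Dunn's rank post-hoc (tie-corrected, Bonferroni)
for continuous variables and chi-square for categorical, switching to
Fisher's exact for 2×2 tables with any expected cell < 5 (larger sparse
tables keep chi-square and are flagged). The endpoint rules are strict
inequalities: a reduction exactly at the band threshold is *not*
residual; a 6-month logMAR exactly at log₁₀(63/20) *is* poor vision
(the 20/63 eye belongs to the low-vision group). Worsening edema
(negative reduction) is residual in every band. ICC is the two-way
mixed-effects, consistency, single-measure form (ICC(3,1) via
pingouin), with paired tables flattened so each subject-feature pair is
one target.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale chosen once: texture
oracles on 100 random ≤12×12 ROIs; parallel-analysis calibration on
100 seeds with 200 permutations (null 200×50; three planted factors at
signal-to-noise 5 in 500×50); planted-cluster recovery on a 120-eye
high-separation cohort with the reduced filter profile (original +
wavelet); bootstrap at B = 100 on 234-row tables with 16 PCs; ANOVA
calibration on 1000 null features; Boruta power at n = 300 with 5
informative features (2 SD shift) among 95 noise and 200 iterations;
logistic recovery at β = 0.56 with n = 5000 and 100 stepwise
simulations at n = 2000. All randomness flows from per-stage seeds
spawned from one master seed; reruns are bit-identical. CSVs are
written shortest-repr and round-trip losslessly under pandas'
round-trip parser.

## Known limitations

Eye-level analysis without within-patient correlation; 2D features
only; no intensity harmonization across devices; the synthetic link
from texture class to outcome is marginal (per-class Bernoulli), so
regression stages on synthetic cohorts see weaker signals than the
planted-cluster stages; published feature-count totals are not
reproduced because the extraction schema is defined by the
configuration (13 derived images × 93 matrix/first-order features + 9
shape = 1218 by default), with determinism guaranteed instead.
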