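# octomics

Unsupervised OCT-radiomics subtyping of diabetic macular edema (DME).

Roughly half of DME eyes respond incompletely to intravitreal anti-VEGF
therapy. This package re-implements, as a tested analysis pipeline, the
idea of stratifying DME eyes *before* treatment from the texture of their
OCT B-scans alone: masked radiomic feature extraction, dimensionality
reduction calibrated against a permutation null, hybrid unsupervised
clustering, resampling-based stability validation, and a three-stage
biomarker selection cascade linking texture phenotypes to treatment
outcomes. Because no patient images are distributable, the package ships a
first-class synthetic cohort generator that emulates the statistical
structure the analysis assumes (four latent texture phenotypes with
cluster-linked outcome prevalences), so every stage is exercisable and
testable end to end.

Intended users: imaging scientists and biostatisticians who want a
reproducible, library-grade version of the OCT-omics workflow — or its
parts (IBSI-style texture features, Horn's parallel analysis, consensus
clustering, Boruta) — without proprietary tooling.

## The pipeline

1. **Features** (`octomics.features`). For each eye, a masked 2D B-scan is
   expanded through a filter bank (wavelet subbands, Laplacian-of-Gaussian
   at σ ∈ {3, 5} mm, logarithm, exponential, gradient, square root, square,
   LBP) and each derived image yields first-order statistics plus GLCM,
   GLRLM, GLSZM, GLDM and NGTDM texture families on a fixed-bin-width
   discretization (levels `⌊(x − min)/w⌋ + 1`); 2D shape descriptors come
   from the mask. The full profile is 1218 named features such as
   `logarithm_gldm_DependenceVariance`
   (`DV = Σᵢⱼ p(i,j)(j − μ)²` over the gray-level/dependence matrix).
   Every matrix feature is verified against exhaustive brute-force
   enumeration to 1e−9.
2. **Reduction** (`octomics.reduction`). Features are z-scored and
   decomposed by PCA; the number of retained components follows Horn's
   parallel analysis — keep the leading components whose eigenvalues exceed
   the 95th percentile of eigenvalues from tables with each column
   independently permuted.
3. **Clustering** (`octomics.clustering`). k is chosen by the elbow of the
   within-cluster sum of squares (second difference of log WSS) and by
   Monti-style consensus clustering (relative change Δ(k) of the area under
   the consensus CDF); the final partition is K-means initialized at Ward
   centroids, labels size-ordered.
4. **Stability** (`octomics.stability`). 500-replicate bootstrap of the
   whole z-score → PCA → K-means pipeline scored by the Adjusted Rand
   Index, plus incremental Gaussian noise injection (image or feature
   domain).
5. **Selection & outcomes** (`octomics.selection`, `octomics.outcomes`).
   Collinearity pruning (|r| > 0.8) → one-way ANOVA across clusters →
   Boruta shadow-feature wrapper per outcome; then univariate and backward
   stepwise logistic regression (entry P < 0.1, stay P < 0.05) with Wald
   odds ratios. Endpoints: residual/recurrent DME by the band-wise CMT
   reduction rule (<10% for ≤400 µm, <15% for 401–500, <20% for 501–600,
   <25% above 600) and poor vision (6-month BCVA ≤ 20/63, logMAR ≥
   log₁₀(63/20)).

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort. With a 120-eye cohort at the default (moderate) phenotype
separation:

```bash
python analysis/01_simulate_cohort.py --seed 0 --n-eyes 120
python analysis/02_extract_features.py --seed 0
python analysis/03_reduce_dimensionality.py --seed 0
python analysis/04_cluster.py --seed 0
python analysis/05_stability.py --seed 0 -B 50
python analysis/06_select_features.py --seed 0
python analysis/07_outcome_models.py --seed 0
```

prints, among other things:

```
parallel analysis retained 8 PCs (84.31% cumulative variance)
elbow k = 2, consensus k = 5; clustered at k = 4
ARI vs planted phenotypes: 0.927
bootstrap ARI (50 replicates): 0.81 ± 0.19 (95% CI 0.52-1.00)
rdme: 474 -> 100 (collinearity) -> 71 (ANOVA) -> 1 confirmed by Boruta
```

Read: the permutation-calibrated PCA keeps 8 components; at moderate
separation the two k selectors legitimately disagree and the analysis
proceeds at the study's k = 4, which still recovers the planted phenotypes
well (ARI 0.93); the partition is bootstrap-stable in the same range a
real cohort shows; and the selection cascade funnels 474 features down to
a single confirmed texture biomarker for residual/recurrent DME. On the
`high_separation_config()` preset the same pipeline recovers the planted
clusters exactly (ARI = 1.0) and both selectors agree on k = 4.

The same stages are callable as a library
(`octomics.pipeline.run_pipeline`) or piecewise, e.g.:

```python
from octomics import generate_cohort, high_separation_config, extract_table
eyes = generate_cohort(high_separation_config(n_eyes=120, seed=7))
features = extract_table(eyes)   # pandas DataFrame, eyes x features
```

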