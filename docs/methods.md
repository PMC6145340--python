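# Methods

This note documents the models and procedures implemented in `micalung`,
the assumptions behind them, the synthetic data they are tested on, and the
numerical conventions used — in the package's own words and notation.

## 1. Voxel-level functional metrics

All density-derived quantities are expressed as per-voxel **air fraction**
f_air ∈ [0, 1] rather than raw Hounsfield units; the linear conversion
f_air = (HU_tissue − HU)/(HU_tissue − HU_air) with HU_air = −1000 and
HU_tissue = 0 is provided, and thresholds are stated on the air-fraction
scale so that they are insensitive to scanner calibration offsets.

**PRM classification.** Given co-registered inspiration (TLC) and
expiration (RV) air-fraction volumes on the same grid, a lung voxel is
classified *Emph* if f_air(TLC) ≥ 0.985, otherwise *fSAD* if
f_air(RV) ≥ 0.90, otherwise *Normal*.  The two thresholds are parameters
(`emph_thr`, `fsad_thr`); the composition order (emphysema takes
precedence) mirrors the standard parametric-response-map construction and
is the only joint rule consistent with mutually exclusive labels.
Emph%/fSAD% are voxel-count percentages per lobe and whole lung; counts are
taken on the (TLC) grid the volumes share.  By construction
Emph% + fSAD% + Normal% = 100 in every region.

**Deformation metrics.** The displacement field u(x) maps RV coordinates to
TLC coordinates, so the deformation gradient F = I + ∇u has det(F) = J > 1
for inflation (whole-lung Jacobians of ~1.3–2.1 are the physiological
range between RV and TLC).  Gradients are central differences in physical
mm, one-sided where a neighbour leaves the mask, zero where a voxel has no
in-mask neighbour along an axis; consequently affine fields are
differentiated *exactly* in the interior and the discretization error lives
in a one-voxel border shell (interior summaries use an eroded mask).
Voxels with J ≤ 0 (folding, non-physical) are excluded from summaries and
counted in a QC report.  The anisotropy index is computed from the
principal stretches λ₁ ≥ λ₂ ≥ λ₃ (square roots of the eigenvalues of FᵀF)
as ADI = √(((λ₁−λ₂)/λ₂)² + ((λ₂−λ₃)/λ₃)²).  This stretch-ratio form is an
adopted convention of this package: it is zero exactly for isotropic
deformation and grows with preferential stretching, which is the property
the downstream analysis uses.

**Volume-change metrics.** V_air(region) = Σ f_air · voxel volume;
ΔV_air(lobe) is the lobe's TLC−RV air-volume difference, ΔV_air^F its
share of the whole-lung change (the lobar shares sum to 1 by
construction), and U/(M+L)|v = (RUL+LUL)/(RML+RLL+LLL) on the lobar
ΔV_air.  β_tissue is the regional mean of 1 − f_air, identically equal to
1 − mean f_air.  The lung-shape ratio is the apical-basal over
ventral-dorsal bounding-box extent of the TLC lung mask in mm, with the
axis convention (x, y, z) = (left-right, ventral-dorsal, apical-basal).

## 2. Airway structural metrics

From each segment's lumen area A (mm²) and perimeter P (mm):
D_h = 4A/P and Cr = 4πA/P².  The circularity convention is fixed by the
isoperimetric inequality — Cr = 1 for a circle and Cr > 1 is rejected as an
inconsistent measurement; healthy central airways sit around 0.96–0.98.
The bifurcation angle θ is measured between the two *daughter* directions
(configurable in principle; parent-daughter angles are not used).  WT and
D_h are divided by predicted tracheal values from a linear healthy-control
reference on sex, age and height; the shipped coefficients are a synthetic
placeholder with physiologically plausible magnitudes (tracheal
WT ≈ 2.5 mm, D_h ≈ 17 mm at age 50, height 170 cm) and are fully
replaceable — the starred values are dimensionless and scale-free, which is
what the analysis relies on.  The region vocabulary is fixed to
{Trachea, LMB, RMB, sRUL, sRML, sRLL, sLUL, sLLL}; unknown labels are
rejected.

## 3. The 69-variable manifest

The default manifest is 32 local ({θ, Cr, WT*, D_h*} × 8 regions) + 30
lobar ({ΔV_air^F, Jacobian, ADI, fSAD%, Emph%, β_tissue} × 5 lobes) + 7
global (fSAD% Total, Emph% Total, lung shape, U/(M+L)|v, Jacobian Total,
ADI Total, β_tissue Total).  The 4 × 8 local composition is this package's
documented default (the exact region-variable composition behind the
"32 local" count is not fixed by the field); the manifest is a data object
and can be overridden from YAML.  Assembly is a pure function that fails
loudly on unresolvable entries or non-finite values; an optional
median-imputation flag is deliberately absent — missing data must be
handled explicitly upstream.

## 4. Clustering chain

`MicaClusterer` runs: column z-scoring with the sample (n−1) standard
deviation, so the covariance of the z-matrix is exactly the correlation
matrix; PCA of that matrix; retention of the leading components; clustering
of the retained scores.

**Component retention.** Three criteria are implemented: Kaiser
(eigenvalues > 1), an automatic scree elbow (maximum second difference of
the eigenvalue curve; components strictly before the elbow are kept), and
Horn's parallel analysis (observed eigenvalues exceeding the mean — or an
optional 95th-percentile — eigenvalue of 100 column-permuted datasets of
the same shape; column permutation preserves marginals while destroying
correlation).  The default rule takes the majority of the three, breaking
full disagreement toward more components with a fallback of 7.  On the
default synthetic cohort parallel analysis retains 7, Kaiser 9 and the
scree elbow 3; the fallback therefore also lands on 7, and seven components
is the fitted default throughout.

**Algorithms.** K-means uses k-means++ (greedy) seeding with 50 restarts;
hierarchical clustering uses Ward linkage on Euclidean distances (the same
variance-minimising objective family as K-means); the Gaussian mixture
uses full covariances with restart-best log-likelihood and a small
covariance regulariser (1e-4).  Labels are 0-based; centroids are reported
in original feature units (per-cluster means of the input matrix).

**Internal validity.** Connectivity (sum over points of 1/j for each of the
L = 10 nearest neighbours not co-clustered; lower is better), the Dunn
index (minimum inter-cluster distance over maximum cluster diameter;
singletons contribute zero diameter, and an all-singleton partition is
assigned +∞ with a warning), and the mean silhouette.  All three are
validated against exhaustive brute-force computation on small instances.

**Choosing k.** `select_k` fits the chain over a k grid and selects the
silhouette maximum; Dunn and connectivity are computed and reported
alongside.  They do not vote: connectivity decreases monotonically toward
the smallest k on nested solutions (its minimum carries no
model-selection signal), and the Dunn index is a min/max statistic with
high sampling variance at cohort sizes of a few hundred.  On the default
synthetic cohort this rule selects k = 4 in 20/20 seeds.

**Bootstrap Jaccard stability.** The chain is fitted on the full data and
refitted on B = 100 nonparametric bootstrap resamples.  Each original
cluster is matched to the replicate cluster maximising
|A∩B|/|A∪B| over the subjects present in the resample (subjects absent
from a resample are excluded from that replicate); per-cluster Jaccard
values are averaged over replicates, and replicates below 0.5 are counted
as dissolutions.  Both the per-cluster means and their minimum are
reported, since a single aggregate can hide one unstable cluster.

**Validation split.** A stratified-by-cluster 50/50 split utility refits
the chain on each half and reports the validation half's label agreement
(after Hungarian matching) between its own clustering and the
training-model prediction.

## 5. Characterization

**Wilks' Λ** for a variable subset is det(W)/det(T) with W the pooled
within-group and T the total cross-product matrix on those columns,
computed via log-determinants; a singular T is rejected with a condition
number diagnostic, and zero within-group variance yields Λ = 0.  The
forward selector adds the variable minimising Λ jointly with the current
set; the entry test is the partial F = ((1−r)/r)·(n−g−p)/(g−1) with
r = Λ_new/Λ_old, default threshold 3.84 (the χ²₁ 5% point), and a path cap
of 10 variables.  Because published rankings may quote either the joint Λ
at entry or the one-variable Λ, both are recorded per step.

**Decision tree.** A Gini CART on a candidate variable set (default: the
seven discriminant variables Jacobian Total, D_h* sLLL, D_h* sRLL,
WT* sRUL, WT* sRML, β_tissue LLL, fSAD% Total), with a leaf-size floor of
5 and cost-complexity pruning applied only as needed to respect the
distinct-variable cap (7).  A one-standard-error cross-validated pruning
mode exists (`prune='1se'`) but is not the default: it selects a markedly
smaller tree (~0.83 mean resubstitution accuracy on the synthetic cohort)
than the ~0.90 resubstitution operating point of the published-style
7-variable distillation this class is meant to reproduce.

**Associations.** Continuous clinical variables are tested with
Kruskal-Wallis (one-way ANOVA available where that is the convention for a
given table); categorical variables with chi-square on the k × levels
contingency table *without* continuity correction; expected cell counts
below 1 trigger a warning and an exact-test flag.  Raw p-values at
α = 0.05 are reported; Benjamini-Hochberg adjustment is available behind a
flag and off by default.  Upper/lower-zone burden ratios use
(RUL+LUL)/(RML+RLL+LLL) per subject; subjects with zero lower-zone burden
yield NaN and are excluded from that summary.

## 6. Synthetic data

**Phantoms.** The lungs are two axis-aligned ellipsoids (semi-axes as
fractions of the grid extent, default grid 44×44×56 at 3 mm), split into
five lobes by fixed fractional planes along the apical-basal axis (right:
0.40/0.65; left: 0.50).  Air fractions are piecewise constant (TLC 0.85,
RV 0.55 by default) with optional spherical plateau blobs: an emphysema
blob (TLC 0.99) and an air-trapping blob (RV ≥ 0.90 with TLC below the
emphysema threshold).  Displacement models are identity, uniform scaling,
per-axis scaling, and a sinusoidal diagonal perturbation
u_i = (s−1)(x_i−c_i) + a_i sin(ω_i x_i), bijective iff |a_i ω_i| < 1
(checked and rejected otherwise) with an analytic per-voxel Jacobian.
Ground truth for every metric is computed from the phantom *definition* —
geometric membership counts and analytic deformation formulas — never
through the voxel-metric code it validates.  For piecewise-constant fields
the fraction and volume ground truths agree with the voxel recomputation
exactly; for deformation metrics they agree to machine precision in the
interior and differ only in the one-voxel border shell.

**Cohort.** The default cohort is 284 current smokers in four clusters of
96/45/88/55 plus 130 healthy controls, with 69 features per subject.  Ten
feature/cluster mean (SD) pairs are published for this regime and are used
verbatim (fSAD% Total, Jacobian Total, β_tissue Total, WT* sRML, ADI RUL,
D_h* sLLL, Emph% Total, ADI Total, ΔV_air^F LLL, Cr LMB, each for four
clusters and healthy controls); they are drawn as independent truncated
normals.  The other 59 features follow a **seven-factor latent rule**:
subject factor scores are N(μ_c, I₇) with cluster c's mean at 3·e_c (the
unit vector along factor c; factors 5–7 are centred for all clusters, and
healthy controls share cluster 1's factor mean, matching their printed
similarity to that cluster); each unprinted feature loads on two factors
(round-robin with an offset, alternating signs, squared loadings summing
to a communality of 0.5) and is mapped to physical units by a
cluster-independent base mean and SD chosen at physiologically plausible
values per metric.  The separation scale 3 was chosen once to mirror the
published between-cluster effect sizes of the printed variables (roughly
1–4 within-cluster SDs).  Truncation clips only to physical ranges
(percentages to [0, 100], Cr to (0, 1], Jacobian > 0, fractions to
[0, 1]); it never encodes cluster structure.  Clinical covariates are drawn
per cluster from the published demographic/PFT/symptom tables (continuous:
clipped normals; ordinal scores and exacerbation counts: rounded clipped
normals; categorical: multinomials on the printed percentages, with
missing categories at probability 0).

**What the generator does and does not emulate.** It reproduces the
*statistical* structure a multiscale QCT cohort presents to the analysis —
cluster locations and spreads of the printed variables, a low-rank
correlated background, physical ranges, class imbalance — so passing tests
demonstrate that the chain recovers known structure at realistic effect
sizes and sample sizes.  It does not simulate CT noise or texture, scanner
effects, registration error, inter-feature correlations beyond the factor
rule (none are published), or any coupling between clinical covariates and
features beyond shared cluster membership; results on real cohorts
additionally depend on those factors.

## 7. Problem sizes and determinism

Default analysis sizes are the study conditions themselves (284 subjects,
69 features, k = 4, 50 K-means restarts, B = 100 bootstrap replicates, 100
parallel-analysis permutations); the multi-seed checks in the test suite
and acceptance script use 20 cohort seeds with 20 restarts per fit, sizes
at which every quantity reported is stable to well within its tolerance.
Every stochastic step is seeded; a single global seed fans out to
per-stage seeds through `numpy.random.default_rng(seed).integers(2**31)`
in a fixed stage order, so identical (config, seed) pairs give
byte-identical numeric outputs.

## 8. Known limitations

- The image registration that produces displacement fields is out of
  scope; fields are inputs (or phantoms).  Airway segmentation likewise —
  segment tables are inputs.
- The tracheal normalisation reference is a synthetic placeholder, not a
  fitted population model.
- PRM voxel counting is done on the shared (TLC) grid; counting on the RV
  grid would require the inverse map and is not implemented.
- Wilks-based selection assumes roughly common within-group covariance;
  with strongly heteroscedastic clusters the ranking is still usable but
  the F thresholds are nominal.
- The Dunn index convention for singleton clusters (zero diameter, +∞ when
  all clusters are singletons) is a choice; comparisons across packages
  should use the silhouette, which has a universal definition.
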