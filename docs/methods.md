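# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Shape model and superimposition

Landmark configurations (k points in ℝ³, µm) are superimposed by
Generalized Procrustes Analysis: each configuration is centred, scaled
to unit centroid size, and iteratively rotated onto the running
consensus; iteration stops when the consensus root-mean-square change
falls below 1e-10 (at most 100 iterations). The consensus is seeded with
the mean of the centred/scaled configurations, which makes GPA a fixed
point of itself on already-aligned input; the first specimen is used as
a fallback seed only if the orientations cancel almost exactly.
Reflections are excluded from fitted rotations by default (landmark
homology is biological, not mirror-symmetric); an `allow_reflection`
flag exists for synthetic work. Original centroid sizes are retained so
allometry can be modelled after superimposition.

Shape PCA is an eigendecomposition of the specimen covariance of the
flattened aligned coordinates, with no phylogenetic correction — the
ordination describes the data; phylogeny enters only in the statistics.
Axis signs follow the convention that the largest-magnitude loading is
positive. Between-group PCA uses the covariance of group mean shapes
(at most g − 1 axes) and projects all specimens.

Thin-plate-spline warping uses the 3D biharmonic kernel U(r) = r, exact
at landmarks and exact for affine maps; the group deviation maps warp a
mesh registered to the overall mean configuration to each group mean and
report per-vertex Euclidean displacement.

## Phylogenetic comparative statistics

All statistics condition on the Brownian tip covariance C (shared
root-to-MRCA path lengths). The GLS transform is the symmetric inverse
square root P = C^(−1/2) from an eigendecomposition rather than a
Cholesky factor: the two differ by a rotation only, so sums of squares
are identical, but the symmetric root is orthogonally invariant (a unit
test asserts the equivalence of the resulting statistics on star trees
against ordinary least squares).

Significance uses residual-randomization permutation (RRPP): residuals
of the reduced model (intercept-only for the overall test) are permuted
across rows on the transformed scale, added back to the reduced fit, and
the model refitted; p = (b + 1)/(B + 1) with ties counted as exceeding
(conservative). Pairwise post hoc tests report Euclidean distances
between GLS-estimated group means with per-pair RRPP nulls, unadjusted
(a Benjamini–Hochberg pass can be applied downstream); B defaults to
1000.

Ancestral states for the convergence measures are joint ML under
Brownian motion, which reduces to harmonic interpolation on the tree
with edge weights 1/length; the linear system is factored once per tree
so the simulation null (tips redrawn from N(1â, C ⊗ R̂), with the rate
matrix R̂ estimated by GLS) costs only back-substitutions. For a focal
pair, Dmax is the maximum distance between any node on one tip's
root-ward path to the MRCA and any node on the other's, tips and MRCA
included; C1 = 1 − Dtip/Dmax, C2 = Dmax − Dtip, C3 and C4 scale C2 by
the summed change along the two paths and over the MRCA clade. Multiple
focal taxa average over pairs; Dmax = 0 yields a missing C1 with a
diagnostic rather than a value.

### Sensitivity to phylogeny-free variance

The D-PGLS machinery assumes residuals with covariance σ²C. Under that
model the permutation test is calibrated (the acceptance suite verifies
a 5% type-I rate on 200 model-conform nulls). When residuals contain an
additional i.i.d. component — e.g. digitisation error — the transform
P amplifies exactly the contrasts (short terminal branches) in which
white noise is over-represented, and rejection rates rise well above
nominal even at noise levels of 5–10% of the Brownian tip SD. This is
the familiar hazard of applying phylogenetic GLS to data whose residuals
lack full phylogenetic signal; it is why digitisation replicates are
averaged before analysis, and why the calibration experiments in this
package use the generator's zero-noise null. Power experiments retain
the noisy defaults.

## Volume allometry

Volumes are natural-logged (the base shifts thresholds, nothing else).
The phylogenetic linear model uses Pagel's λ: residual covariance
σ²(λC + (1 − λ) diag C), λ estimated by bounded scalar ML with σ²
profiled out; coefficient covariance uses the unbiased residual variance
(n − q). Slope homogeneity is a likelihood-ratio test of the
mode × covariate interaction (χ², k − 1 df), each model with its own λ̂.

The pipeline's decision gate mirrors the analysis logic the method
demands: the Johnson–Neyman procedure (which has no phylogenetically
informed version) is applied only when homogeneity is rejected **and**
λ̂ < 0.05; otherwise the common-slope phylogenetic ANCOVA path is
reported. The branch taken is logged and recorded in the report. JN
boundaries are the roots of
(Δb² − t²V_bb)x² + 2(ΔbΔa − t²V_ab)x + (Δa² − t²V_aa) = 0 with
t = t(α/2, n − 4) (two lines, two parameters each; df configurable);
degenerate quadratics fall back to sign analysis, and intervals are
clipped to the observed covariate range. A grid-scan-plus-bisection
oracle in the tests confirms the roots to 1e-6.

## Purkinje-cell layout

Depth percent = 100 · (distance to the inner granule-cell-layer border)
/ (local molecular-layer thickness). Kruskal–Wallis is tie-corrected;
for pooled N ≤ 10 the p-value comes from exhaustive enumeration of
group assignments instead of the χ² approximation. The DSCF post hoc
refers the tie-corrected standardised rank-sum to the Studentized range
with k groups (infinite df); pairs with pooled N ≤ 10 likewise switch
to exact rank-sum enumeration, where the asymptotic reference is
unreliable. Cells are pooled per species across individuals (individual
ids are retained in the table for sensitivity runs).

Positioning patterns are the connected components of the graph linking
species pairs with p ≥ α (default 0.05): deterministic and
order-independent. When a component contains a significantly different
pair (non-transitive graph) the result carries a flag. Patterns are
labelled I, II, … by ascending median depth, and a confirmation
Kruskal–Wallis re-tests the derived patterns against each other.

## Expression

Genes are retained if any species exceeds 0.5 FPKM strictly ("above" is
exclusive; a gene at exactly 0.5 is dropped). Z-scoring is per gene with
sample SD; constant rows become zeros and are flagged. Distances are
Euclidean, 1 − Pearson, or 1 − Spearman; linkage defaults to average.
The gene-archetype analysis clusters log2(FPKM + 1) levels with Ward
linkage: the three archetypes (shared-high, shared-low,
mode-differential) are level-and-pattern clusters, which a compactness
objective recovers where average linkage chains, and which z-scored rows
cannot distinguish at all (scaling erases the level separating
shared-high from shared-low). Species dendrograms use correlation
distances on the filtered FPKM matrix.

AU support: genes are resampled with replacement at scales
r ∈ {0.5, …, 1.4}; per internal node, BP(r) is the fraction of
replicates containing the identical tip set; z(r) = Φ⁻¹(1 − BP(r)) is
fitted as v√r + c/√r by weighted least squares (delta-method binomial
weights) over the scales with informative proportions (0 < BP < 1), and
AU = 1 − Φ(v − c). All-0/all-1 profiles are resolved by the ε rule
(ε = 1/(2·iterations)) with a flag, since they pin z at the clipping
value and leave the two basis functions indistinguishable.

GO enrichment is the upper-tail hypergeometric probability P(X ≥ k) per
term with BH adjustment across terms; reported terms have raw p < 0.01
and at least ten cluster genes carrying the term ("ten genes" is read as
cluster-side). No GO-DAG propagation: terms are taken as annotated.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuned per experiment.

- **Tree**: pure birth, unit rate, depth scaled to 1; parameter-free by
  design, and any user Newick can replace it.
- **Landmarks**: per species, base shape + Brownian drift + a fixed
  per-mode displacement field + an allometric deformation ×
  log-size deviation + i.i.d. session noise — all in shape units of
  order 1, then scaled to µm by the species size factor. Defaults:
  Brownian tip SD 0.05 per coordinate (phylogeny is the dominant
  signal, and the default bundle shows significant multivariate K),
  mode displacement 0.03 per landmark (three times the digitisation
  noise SD of 0.01), allometric coefficient 0.015 (allometry predicts
  roughly a tenth to a fifth of shape variation).
- **Volumes**: per-mode log-log lines whose default slopes
  (1.20 … 0.85) cross inside the observed brain-size range, with
  residual SD 0.12 split between a Brownian and an independent
  component by `volume_lambda`. The default λ = 0 emulates volumetric
  residuals without phylogenetic signal — the regime in which the
  Johnson–Neyman branch (rather than common-slope ANCOVA) is the
  appropriate analysis, which is exactly the gate the pipeline applies.
- **Cell depths**: Beta-distributed depth percentages per scattering
  archetype — I (10%, κ=60), II (22%, κ=25), III (32%, κ=7),
  IV (50%, κ=2 = uniform). Bounded support matches the 0–100% scale,
  and κ=2 at mean 50 makes "totally scattered" literally uniform.
  Neighbouring archetypes are kept at pairwise rank-AUC ≥ ~0.68: the
  four patterns represent significantly different positioning regimes,
  not points on a continuum. 250–750 cells per species; per-cell
  molecular-layer thickness is log-normal around 120 µm.
- **Expression**: log-normal FPKM (positivity and skew of FPKM data);
  archetype 1 high in all species, archetype 2 low in all, archetype 3
  shifted per mode with the shifts centred per gene — differential
  genes vary around their own mean level, so the archetype is a pattern
  across modes rather than an abundance change. One GO term
  ("locomotory behaviour") is planted preferentially in archetype-3
  genes.
- **Seeding**: one integer seed; each generator draws from a
  deterministically derived sub-stream, so bundles are bit-identical
  under a fixed seed regardless of which generators run or in what
  order.

What the generator does **not** emulate: real brain geometry (landmarks
are not anatomically arranged), digitisation error correlated along
structures, per-individual variation within species (one configuration
per species by default; replicates are optional and i.i.d.), missing
data, unequal sampling across modes, GO-term hierarchy, and
phylogenetic signal in expression noise (expression residuals are
i.i.d., so the species dendrogram's mode grouping is structural, not a
victory over a competing tree signal). Tests that pass on these bundles
validate the statistical machinery under its assumptions; they do not
show that real data satisfy those assumptions.

## Problem sizes

The acceptance script runs the full chain at the default study scale
(40 species, 66 landmarks, ~20k cells, 630 genes) with 999 permutations
for the permutation tests, 500 simulations for the convergence null,
and 1000 bootstrap iterations for AU support, plus 100-replicate
calibration and power experiments at 99 permutations each. The test
suite uses 200-replicate calibration/power runs and smaller bundles for
unit-level checks; these sizes keep single-CPU runtimes in the minutes
while leaving binomial confidence bands tight enough to be informative.

## Package shape

The package is organised as one module per analysis stage with free
functions returning rich result objects (`SignalResult`, `AnovaResult`,
`AncovaFit` with `summary()` tables, …) rather than a single
statsmodels-style Model/Results pair: the artifact is a multi-stage
pipeline whose stages share no single fitted model. The fitted pieces
(D-PGLS, the λ-ANCOVA) nevertheless follow the fit-returns-results
idiom, and the pipeline module composes the stages declaratively.
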