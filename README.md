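# cerebrotype

Multi-level ecomorphology of the cerebellum: does a brain structure's
shape, size, cellular architecture and gene expression track a species'
ecology — here, its locomotor mode — rather than its phylogeny?

`cerebrotype` implements the complete analysis chain for that question on
comparative data from many species, exercised end-to-end on a synthetic
data generator that emulates the structure of such a study (a panel of
~40 squamate species in seven locomotor categories). It is aimed at
evolutionary morphologists and comparative neuroanatomists who have:

- 3D landmark configurations per specimen (here: 61 whole-brain
  landmarks plus 5 cerebellar interface landmarks),
- a dated phylogeny of the sampled species,
- whole-organ and sub-organ volumes,
- per-cell positional measurements (Purkinje-cell depths in the
  molecular layer), and
- a genes × species expression matrix of one-to-one orthologs.

## What it computes

**Shape.** Generalized Procrustes Analysis superimposes landmark
configurations, separating shape from centroid size
CS = √Σᵢ‖xᵢ − x̄‖². Shape PCA, between-group PCA, bootstrap confidence
ellipses, and thin-plate-spline warping (3D kernel U(r) = r) of a
surface mesh to group mean shapes with per-vertex deviation fields.

**Phylogenetic statistics.** With C the Brownian-motion tip covariance of
the tree and Y the shape variables:

- multivariate phylogenetic signal
  K = [tr(DᵀD)/tr(DᵀC⁻¹D)] / [(tr C − n/(1ᵀC⁻¹1))/(n − 1)],
  D = Y − 1â (GLS mean), with a tip-shuffling permutation test;
  K = 1 under pure Brownian motion;
- D-PGLS regression and ANOVA: transform Ỹ = C^(−1/2)Y, X̃ = C^(−1/2)X,
  F from sums of squares on the transformed scale, significance by
  residual-randomization permutation (RRPP), pairwise post hoc distances
  between GLS group means;
- Stayton's distance-based convergence measures C1–C4 with ML ancestral
  states under Brownian motion and a simulation null.

**Volumes.** Per-mode log–log PGLS regression lines with Pagel's λ by
maximum likelihood, a likelihood-ratio slope-homogeneity test, and —
when slopes are heterogeneous and λ ≈ 0 — the Johnson–Neyman region of
significance: {x : d(x)²/v(x) ≥ t²} solved in closed form from the
coefficient covariance. A phylogenetic ANOVA of the cerebellum-to-brain
volume ratio complements the lines.

**Cell layout.** Per-cell depth normalised to the local molecular-layer
thickness (0% = granule-cell-layer border, 100% = pial surface);
Kruskal–Wallis with tie correction (exact enumeration for pooled
N ≤ 10); Dwass–Steel–Critchlow–Fligner pairwise post hoc (Studentized
range reference); species partitioned into positioning patterns
(ordered monolayer → totally scattered) as connected components of the
not-significantly-different graph.

**Expression.** 0.5-FPKM ortholog filtering, per-gene z-scoring,
hierarchical clustering of genes (expression archetypes) and species
(expression phylogeny), approximately-unbiased (AU) node support by
multiscale bootstrap (fit z(r) = v√r + c/√r, AU = 1 − Φ(v − c)), and
hypergeometric GO enrichment with Benjamini–Hochberg correction.

**Synthetic data.** `simulate_bundle` generates a full study — pure-birth
tree, Brownian landmark evolution with mode mean shifts and allometry,
per-mode volume allometries, four Purkinje-scattering archetypes (Beta
distributed depths), a 630-gene expression matrix with three archetypes,
and GO annotations — with a `truth` record for parameter-recovery tests.

## Worked example

```python
import numpy as np
from cerebrotype import (SimConfig, simulate_bundle, gpa, shape_pca,
                         k_mult, phylo_procrustes_anova,
                         slope_homogeneity_test, dscf_posthoc,
                         partition_patterns)

bundle = simulate_bundle(SimConfig(seed=42))        # 40 species, 7 modes
aligned = gpa(bundle.landmarks, "cerebellum")       # 21-landmark subset
space = shape_pca(aligned)
print(np.round(space.percent_variance[:3], 2))      # [16.95 12.57 11.38]

signal = k_mult(aligned, bundle.tree, permutations=999, seed=42)
print(signal.summary())
# Multivariate phylogenetic signal
#   K = 0.5713
#   p = 0.001  (999 permutations)

anova = phylo_procrustes_anova(aligned, bundle.modes, bundle.tree,
                               permutations=999, seed=42)
print(f"{anova.r_squared:.3f} {anova.F:.2f} {anova.p:.3f}")
# 0.456 4.61 0.001

p_hom, fit = slope_homogeneity_test(bundle.volumes, bundle.tree)
print(f"{p_hom:.3g} {fit.lam:.3f}")                 # 9.49e-08 0.091

groups = partition_patterns(dscf_posthoc(bundle.depths), bundle.depths)
print(sorted(set(groups.patterns.values())))        # ['I', 'II', 'III', 'IV']
```

Reading the output: shape variation carries significant phylogenetic
signal (K = 0.57, p = 0.001) *and* a significant locomotor-mode effect
(R² = 0.46, p = 0.001); the volume allometries violate slope homogeneity
(p ≈ 10⁻⁷), so mode comparisons go through the Johnson–Neyman region
rather than a common-slope ANCOVA; and the Purkinje-cell depth
distributions partition the species into the four generating scattering
patterns.

A YAML-driven run of all stages is available from the shell:

```sh
cerebrotype simulate --seed 1 --out data/
cerebrotype run --config pipeline.yaml
```

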