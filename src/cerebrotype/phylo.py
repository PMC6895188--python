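"""Phylogenetic comparative statistics on multivariate shape data.

Shared tip ancestry makes species non-independent; under Brownian motion
the tip values of a trait covary proportionally to shared branch length
(the matrix C).  Everything here conditions on C:

* ``k_mult`` — a multivariate generalisation of Blomberg's K, the ratio of
  observed phylogenetic signal to the Brownian expectation (K = 1 under
  pure Brownian motion), with a tip-shuffling permutation test.
* ``pgls_shape_regression`` / ``phylo_procrustes_anova`` — multivariate
  regression / ANOVA under phylogenetic generalised least squares
  (D-PGLS), with significance from residual-randomization permutation
  (RRPP) and pairwise post hoc distances between GLS group means.
* ``convergence_c_measures`` — Stayton's distance-based convergence
  statistics C1–C4 with ancestral states reconstructed by ML under
  Brownian motion and a simulation-based null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .morphometry import AlignedShapes
from .trees import PhyloTree

__all__ = [
    "SignalResult",
    "AnovaResult",
    "ConvergenceResult",
    "k_mult",
    "pgls_shape_regression",
    "phylo_procrustes_anova",
    "convergence_c_measures",
]


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

@dataclass
class SignalResult:
    """Multivariate phylogenetic signal (K statistic) with permutation p."""

    K: float
    p: float
    n_permutations: int
    K_permuted: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        return (f"Multivariate phylogenetic signal\n"
                f"  K = {self.K:.4f}\n"
                f"  p = {self.p:.4g}  ({self.n_permutations} permutations)")


@dataclass
class AnovaResult:
    """D-PGLS fit: effect sums of squares, F, RRPP p, pairwise post hoc."""

    SS_effect: float
    SS_total: float
    F: float
    p: float
    df_effect: int
    df_resid: int
    n_permutations: int
    term: str = "effect"
    pairwise: dict[tuple[str, str], tuple[float, float]] | None = None
    residuals: np.ndarray | None = field(default=None, repr=False)
    coefficients: np.ndarray | None = field(default=None, repr=False)

    @property
    def r_squared(self) -> float:
        """Proportion of (GLS-centred) variation predicted by the effect."""
        return self.SS_effect / self.SS_total if self.SS_total > 0 else 0.0

    def summary(self) -> str:
        lines = [
            f"Phylogenetic GLS {self.term}",
            f"  SS_effect = {self.SS_effect:.6g}   SS_total = {self.SS_total:.6g}",
            f"  R^2 = {self.r_squared:.4f}   "
            f"F({self.df_effect}, {self.df_resid}) = {self.F:.4f}",
            f"  p = {self.p:.4g}  ({self.n_permutations} permutations)",
        ]
        if self.pairwise:
            lines.append("  pairwise (GLS mean distance, p):")
            for (a, b), (d, p) in sorted(self.pairwise.items()):
                lines.append(f"    {a} vs {b}: d = {d:.5g}, p = {p:.4g}")
        return "\n".join(lines)


@dataclass
class ConvergenceResult:
    """Stayton C1–C4 with Brownian-motion simulation p-values."""

    C1: float
    C2: float
    C3: float
    C4: float
    p1: float
    p2: float
    p3: float
    p4: float
    n_simulations: int
    focal_taxa: list[str] = field(default_factory=list)

    def summary(self) -> str:
        rows = [
            ("C1 (fraction of max divergence closed)", self.C1, self.p1),
            ("C2 (absolute divergence closed)", self.C2, self.p2),
            ("C3 (C2 / lineage path change)", self.C3, self.p3),
            ("C4 (C2 / clade total change)", self.C4, self.p4),
        ]
        out = [f"Convergence among {len(self.focal_taxa)} focal taxa "
               f"({self.n_simulations} BM simulations)"]
        for name, v, p in rows:
            out.append(f"  {name}: {v:.4f}  p = {p:.4g}")
        return "\n".join(out)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _species_matrix(shapes: AlignedShapes) -> tuple[np.ndarray, list[str]]:
    """Flattened coordinates with exactly one configuration per species."""
    species = list(shapes.species)
    if len(set(species)) != len(species):
        dup = sorted({s for s in species if species.count(s) > 1})
        raise ValueError(
            f"replicate specimens per species: {dup}; average replicates first")
    return shapes.flat(), species


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition.

    The symmetric root (rather than a Cholesky factor) is used so that the
    GLS transform is orthogonally invariant; the two differ only by a
    rotation and give identical sums of squares.
    """
    w, V = np.linalg.eigh(C)
    if w.min() <= 0:
        raise np.linalg.LinAlgError("covariance matrix is not positive definite")
    return (V / np.sqrt(w)) @ V.T


def _perm_pvalue(null: np.ndarray, observed: float) -> float:
    """(b+1)/(B+1) permutation p, ties counted as >= (conservative)."""
    b = int(np.sum(null >= observed - 1e-12))
    return (b + 1) / (len(null) + 1)


def _gls_mean(Y: np.ndarray, Cinv: np.ndarray) -> np.ndarray:
    one = np.ones(Y.shape[0])
    denom = one @ Cinv @ one
    return (one @ Cinv @ Y) / denom


# --------------------------------------------------------------------------
# phylogenetic signal
# --------------------------------------------------------------------------

def k_mult(shapes: AlignedShapes | np.ndarray, tree: PhyloTree, *,
           species: list[str] | None = None,
           permutations: int = 1000,
           seed: int | np.random.Generator | None = None) -> SignalResult:
    """Multivariate K: observed vs Brownian-expected phylogenetic signal.

    With Y the species-by-variables data, C the tree covariance, and
    a the GLS mean, K is the ratio of the observed signal ratio
    ``tr(D'D)/tr(D'C^-1 D)`` (D = Y - 1a) to its Brownian-motion
    expectation ``(tr(C) - n/sum(C^-1)) / (n - 1)``.  On a star tree with
    unit depths C = I and K = 1 identically.  The permutation null shuffles
    data rows across tips.
    """
    if isinstance(shapes, AlignedShapes):
        Y, species = _species_matrix(shapes)
    else:
        Y = np.atleast_2d(np.asarray(shapes, dtype=float))
        if species is None:
            raise ValueError("species order required with a bare data matrix")
    C = tree.covariance(species, prune_extra=True)
    Cinv = np.linalg.inv(C)
    n = len(species)
    one = np.ones(n)
    expected = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)

    def stat(Ymat: np.ndarray) -> float:
        D = Ymat - _gls_mean(Ymat, Cinv)
        denom = np.einsum("ij,ij->", D, Cinv @ D)
        if denom <= 0:
            return 0.0
        return float((np.einsum("ij,ij->", D, D) / denom) / expected)

    K_obs = stat(Y)
    rng = np.random.default_rng(seed)
    K_perm = np.empty(permutations)
    for b in range(permutations):
        K_perm[b] = stat(Y[rng.permutation(n)])
    return SignalResult(K_obs, _perm_pvalue(K_perm, K_obs), permutations, K_perm)


# --------------------------------------------------------------------------
# D-PGLS engine
# --------------------------------------------------------------------------

def _dpgls(Y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray,
           C: np.ndarray, permutations: int,
           rng: np.random.Generator,
           pair_contrasts: list[tuple[tuple[str, str], np.ndarray]] | None = None,
           ) -> tuple[AnovaResult, dict | None]:
    """Core D-PGLS fit with RRPP.

    Transforms data and design by P = C^(-1/2) and compares the full model
    against the reduced one.  RRPP permutes the reduced-model residuals (in
    the transformed space), adds them back to the reduced fit, and refits,
    giving the null distribution of F and of any pairwise mean distances.
    """
    n = Y.shape[0]
    P = _inv_sqrt(C)
    Yt, Xf, Xr = P @ Y, P @ X_full, P @ X_red

    pinv_f = np.linalg.pinv(Xf)
    pinv_r = np.linalg.pinv(Xr)
    Hf = Xf @ pinv_f
    Hr = Xr @ pinv_r
    q_f = int(round(np.trace(Hf)))
    q_r = int(round(np.trace(Hr)))
    df1 = q_f - q_r
    df2 = n - q_f
    if df1 < 1:
        raise ValueError("full model adds no parameters over the reduced model")
    if df2 < 1:
        raise ValueError("no residual degrees of freedom")

    fit_r = Hr @ Yt
    E_r = Yt - fit_r

    def decompose(Ymat: np.ndarray):
        sse_f = np.sum((Ymat - Hf @ Ymat) ** 2)
        sse_r = np.sum((Ymat - Hr @ Ymat) ** 2)
        ss_eff = sse_r - sse_f
        F = (ss_eff / df1) / (sse_f / df2) if sse_f > 0 else np.inf
        return ss_eff, sse_r, sse_f, F

    ss_eff, ss_tot, sse_f, F_obs = decompose(Yt)

    def pair_dists(Ymat: np.ndarray) -> np.ndarray:
        B = pinv_f @ Ymat
        return np.array([np.linalg.norm(con @ B) for _, con in pair_contrasts])

    d_obs = pair_dists(Yt) if pair_contrasts else None

    F_null = np.empty(permutations)
    d_null = (np.zeros((permutations, len(pair_contrasts)))
              if pair_contrasts else None)
    for b in range(permutations):
        Ystar = fit_r + E_r[rng.permutation(n)]
        F_null[b] = decompose(Ystar)[3]
        if pair_contrasts:
            d_null[b] = pair_dists(Ystar)

    p = _perm_pvalue(F_null, F_obs)
    beta = pinv_f @ Yt                   # GLS coefficients
    resid = Y - X_full @ beta            # original-scale residuals for reuse

    pairwise = None
    if pair_contrasts:
        pairwise = {}
        for j, (names, _) in enumerate(pair_contrasts):
            pairwise[names] = (float(d_obs[j]),
                               _perm_pvalue(d_null[:, j], d_obs[j]))

    result = AnovaResult(float(ss_eff), float(ss_tot), float(F_obs), p,
                         df1, df2, permutations, pairwise=pairwise,
                         residuals=resid, coefficients=beta)
    return result, pairwise


def pgls_shape_regression(shapes: AlignedShapes | np.ndarray, covariate,
                          tree: PhyloTree, *,
                          species: list[str] | None = None,
                          permutations: int = 1000,
                          seed: int | np.random.Generator | None = None,
                          ) -> AnovaResult:
    """Multivariate PGLS regression of shape onto a scalar covariate.

    The standard test for evolutionary allometry regresses the Procrustes
    shape variables onto (log) centroid size under the Brownian covariance;
    ``r_squared`` is the "percentage predicted" of that regression and
    ``residuals`` the size-corrected shape data reusable downstream.
    """
    if isinstance(shapes, AlignedShapes):
        Y, species = _species_matrix(shapes)
    else:
        Y = np.atleast_2d(np.asarray(shapes, dtype=float))
        if species is None:
            raise ValueError("species order required with a bare data matrix")
    x = np.asarray([covariate[s] for s in species] if isinstance(covariate, dict)
                   else covariate, dtype=float)
    if x.shape != (len(species),):
        raise ValueError("covariate must supply one value per species")
    if not np.isfinite(x).all():
        raise ValueError("covariate contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    C = tree.covariance(species, prune_extra=True)
    n = len(species)
    X_full = np.column_stack([np.ones(n), x])
    X_red = np.ones((n, 1))
    rng = np.random.default_rng(seed)
    res, _ = _dpgls(Y, X_full, X_red, C, permutations, rng)
    res.term = "regression"
    return res


def phylo_procrustes_anova(shapes: AlignedShapes | np.ndarray, groups,
                           tree: PhyloTree, *,
                           species: list[str] | None = None,
                           covariate=None,
                           permutations: int = 1000,
                           seed: int | np.random.Generator | None = None,
                           pairwise: bool = True) -> AnovaResult:
    """Phylogenetic Procrustes ANOVA of shape on a grouping factor.

    Group effects are tested by D-PGLS with a group-indicator design and
    RRPP; post hoc tests report Euclidean distances between GLS-estimated
    group means, each with its own RRPP p-value (unadjusted, as is usual
    for these tables; adjust downstream if desired).  An optional scalar
    covariate (e.g. log centroid size) is included in both models, making
    the group test allometry-corrected.
    """
    if isinstance(shapes, AlignedShapes):
        Y, species = _species_matrix(shapes)
    else:
        Y = np.atleast_2d(np.asarray(shapes, dtype=float))
        if species is None:
            raise ValueError("species order required with a bare data matrix")
    g = np.asarray([groups[s] for s in species] if isinstance(groups, dict)
                   else groups)
    if g.shape != (len(species),):
        raise ValueError("groups must supply one label per species")
    levels = sorted(set(g.tolist()))
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    singletons = [lv for lv in levels if np.sum(g == lv) < 2]
    if singletons:
        import warnings
        warnings.warn(f"groups with a single species: {singletons}",
                      stacklevel=2)

    n = len(species)
    G = np.stack([(g == lv).astype(float) for lv in levels], axis=1)
    cols = [G]
    red_cols = [np.ones((n, 1))]
    if covariate is not None:
        x = np.asarray([covariate[s] for s in species]
                       if isinstance(covariate, dict) else covariate,
                       dtype=float).reshape(-1, 1)
        cols.append(x)
        red_cols.append(x)
    X_full = np.hstack(cols)
    X_red = np.hstack(red_cols)

    contrasts = None
    if pairwise:
        k = len(levels)
        contrasts = []
        for i in range(k):
            for j in range(i + 1, k):
                con = np.zeros(X_full.shape[1])
                con[i], con[j] = 1.0, -1.0
                contrasts.append(((levels[i], levels[j]), con))

    C = tree.covariance(species, prune_extra=True)
    rng = np.random.default_rng(seed)
    res, _ = _dpgls(Y, X_full, X_red, C, permutations, rng,
                    pair_contrasts=contrasts)
    res.term = "ANOVA (groups)"
    return res


# --------------------------------------------------------------------------
# convergence measures
# --------------------------------------------------------------------------

class _AncestralSolver:
    """Prefactored ML ancestral-state solver for one tree and species order.

    The BM likelihood is a product of Gaussian increments over edges, so
    the joint ML states minimise sum_e ||x_child - x_parent||^2 / l_e —
    harmonic interpolation on the tree with edge weights 1/length.  The
    tree-dependent system is factored once; repeated calls (e.g. inside a
    simulation null) only back-substitute.
    """

    def __init__(self, tree: PhyloTree, species: list[str]):
        et = tree.edge_table()
        self._et = et
        n_nodes = et.n_nodes
        self._tip_rows = [(et.tip_index[s], r) for r, s in enumerate(species)]
        tip_row = dict(self._tip_rows)
        internal = [i for i in range(n_nodes) if et.children[i]]
        self._pos = {node: r for r, node in enumerate(internal)}
        m = len(internal)
        L = np.zeros((m, m))
        W = np.zeros((m, len(species)))
        for child in range(1, n_nodes):
            par = et.parent[child]
            w = 1.0 / et.length[child]
            i = self._pos[par]
            L[i, i] += w
            if child in self._pos:
                j = self._pos[child]
                L[i, j] -= w
                L[j, i] -= w
                L[j, j] += w
            else:
                W[i, tip_row[child]] += w
        self._factor = sla.cho_factor(L)
        self._W = W
        self._n_nodes = n_nodes

    def states(self, tip_values: np.ndarray) -> np.ndarray:
        """All-node states (preorder numbering) for a tips-by-traits matrix."""
        Y = np.atleast_2d(np.asarray(tip_values, dtype=float))
        sol = sla.cho_solve(self._factor, self._W @ Y)
        states = np.zeros((self._n_nodes, Y.shape[1]))
        for node, r in self._pos.items():
            states[node] = sol[r]
        for node, r in self._tip_rows:
            states[node] = Y[r]
        return states


def ancestral_states_bm(tree: PhyloTree, tip_values: np.ndarray,
                        species: list[str]) -> np.ndarray:
    """ML ancestral states under Brownian motion for all tree nodes."""
    return _AncestralSolver(tree, species).states(tip_values)


def _c_measures_from_states(tree: PhyloTree, states: np.ndarray,
                            focal_nodes: tuple[int, int]) -> tuple[float, ...]:
    """C1–C4 for one focal tip pair given phenotypes at every node.

    Dtip is the tip-tip distance; Dmax the maximum distance between any
    node on one tip's root-ward path to the MRCA and any node on the
    other's (tips and MRCA included).  C1 = 1 - Dtip/Dmax is the fraction
    of the maximum past divergence closed by subsequent evolution; C2 its
    absolute counterpart; C3 and C4 scale C2 by the summed phenotypic
    change along the two paths and over the whole MRCA clade respectively.
    """
    et = tree.edge_table()
    i, j = focal_nodes

    # walk both tips to their MRCA
    anc_i = []
    a = i
    while a != -1:
        anc_i.append(a)
        a = et.parent[a]
    path_j = [j]
    while path_j[-1] not in anc_i:
        path_j.append(et.parent[path_j[-1]])
    mrca = path_j[-1]
    path_i = anc_i[:anc_i.index(mrca) + 1]

    Dtip = float(np.linalg.norm(states[i] - states[j]))
    Dmax = max(float(np.linalg.norm(states[u] - states[v]))
               for u in path_i for v in path_j)
    if Dmax <= 0:
        return (np.nan, 0.0, 0.0, 0.0, Dtip, Dmax, mrca)
    C1 = 1.0 - Dtip / Dmax
    C2 = Dmax - Dtip
    path_change = sum(
        float(np.linalg.norm(states[path[s]] - states[path[s + 1]]))
        for path in (path_i, path_j) for s in range(len(path) - 1))
    C3 = C2 / path_change if path_change > 0 else 0.0
    clade_change = sum(float(np.linalg.norm(states[c] - states[par]))
                       for par, c, _ in tree.clade_edges(mrca))
    C4 = C2 / clade_change if clade_change > 0 else 0.0
    return (C1, C2, C3, C4, Dtip, Dmax, mrca)


def _c_measures(tree: PhyloTree, states: np.ndarray,
                focal_idx: list[int]) -> np.ndarray:
    vals = []
    for a in range(len(focal_idx)):
        for b in range(a + 1, len(focal_idx)):
            c1, c2, c3, c4, *_ = _c_measures_from_states(
                tree, states, (focal_idx[a], focal_idx[b]))
            vals.append((c1, c2, c3, c4))
    return np.nanmean(np.asarray(vals, dtype=float), axis=0)


def convergence_c_measures(data: AlignedShapes | np.ndarray, tree: PhyloTree,
                           focal_taxa: list[str], *,
                           species: list[str] | None = None,
                           n_sim: int = 1000,
                           seed: int | np.random.Generator | None = None,
                           ) -> ConvergenceResult:
    """Stayton's C1–C4 convergence measures for a set of focal taxa.

    Phenotypes (aligned shape variables or ordination scores) are assigned
    to internal nodes by ML ancestral-state reconstruction under Brownian
    motion; C values for each focal pair compare present tip similarity to
    the maximum past divergence along the pair's root-ward paths, and are
    averaged over pairs.  p-values come from ``n_sim`` Brownian-motion
    simulations on the tree with the evolutionary rate matrix estimated
    from the data ((s+1)/(S+1) with ties counted as exceeding).
    """
    if isinstance(data, AlignedShapes):
        Y, species = _species_matrix(data)
    else:
        Y = np.atleast_2d(np.asarray(data, dtype=float))
        if species is None:
            raise ValueError("species order required with a bare data matrix")
    if len(focal_taxa) < 2:
        raise ValueError("need at least 2 focal taxa")
    missing = set(focal_taxa) - set(species)
    if missing:
        raise KeyError(f"focal taxa not in data/tree: {sorted(missing)}")

    et = tree.edge_table()
    focal_idx = [et.tip_index[t] for t in focal_taxa]

    solver = _AncestralSolver(tree, species)
    obs = _c_measures(tree, solver.states(Y), focal_idx)

    # BM null: tips ~ N(1 a, C (x) R), R estimated by GLS from the data
    C = tree.covariance(species)
    Cinv = np.linalg.inv(C)
    a = _gls_mean(Y, Cinv)
    D = Y - a
    n, p = Y.shape
    R = D.T @ Cinv @ D / (n - 1)
    Lc = np.linalg.cholesky(C)
    wR, VR = np.linalg.eigh(R)
    Lr = VR * np.sqrt(np.clip(wR, 0, None))

    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, 4))
    for s in range(n_sim):
        Ysim = a + Lc @ rng.standard_normal((n, p)) @ Lr.T
        sims[s] = _c_measures(tree, solver.states(Ysim), focal_idx)

    ps = [
        _perm_pvalue(sims[~np.isnan(sims[:, k]), k], obs[k])
        if np.isfinite(obs[k]) else np.nan
        for k in range(4)
    ]
    return ConvergenceResult(*(float(v) for v in obs), *ps, n_sim,
                             list(focal_taxa))
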