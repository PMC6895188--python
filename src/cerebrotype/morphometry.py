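"""3D landmark geometric morphometrics.

Shape is what remains of a landmark configuration after translation, scale
and orientation are removed.  The work-horses here are Generalized
Procrustes Analysis (iterative superimposition of many configurations onto
a consensus), centroid size (the size variable GPA factors out), principal
component ordinations of the aligned coordinates, and thin-plate-spline
warping used to carry a surface mesh from one landmark configuration to
another (e.g. from the overall mean shape to a group mean shape).

Conventions: landmark indices are 0-based; coordinates are in µm in a
right-handed frame; reflections are never part of a fitted rotation unless
explicitly allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LandmarkSet",
    "AlignedShapes",
    "ShapeSpace",
    "average_replicates",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "shape_pca",
    "between_group_pca",
    "group_confidence_ellipse",
    "find_mean_spec",
    "tps_warp",
    "group_mean_deviation_map",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Per-specimen 3D landmark configurations.

    Parameters
    ----------
    coords
        Array ``(n_specimens, n_landmarks, 3)`` of coordinates (µm).
    specimens
        Specimen identifiers, one per configuration.
    species
        Species identifier per specimen (several specimens may share one).
    subsets
        Named landmark-index subsets, e.g. a whole-brain set and a
        cerebellum set that adds extra interface landmarks.  A subset named
        ``"all"`` covering every landmark is always available.
    """

    coords: np.ndarray
    specimens: list[str]
    species: list[str]
    subsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_specimens, n_landmarks, 3)")
        if len(self.specimens) != self.coords.shape[0]:
            raise ValueError("specimens length does not match coords")
        if len(self.species) != self.coords.shape[0]:
            raise ValueError("species length does not match coords")
        if not np.isfinite(self.coords).all():
            raise ValueError("landmark coordinates must be finite")
        self.subsets = {k: np.asarray(v, dtype=int) for k, v in self.subsets.items()}
        self.subsets.setdefault("all", np.arange(self.coords.shape[1]))

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def subset(self, name: str) -> "LandmarkSet":
        if name not in self.subsets:
            raise KeyError(f"unknown landmark subset {name!r}; "
                           f"have {sorted(self.subsets)}")
        idx = self.subsets[name]
        return LandmarkSet(self.coords[:, idx, :], list(self.specimens),
                           list(self.species), {"all": np.arange(len(idx))})


@dataclass
class AlignedShapes:
    """Procrustes-superimposed configurations plus the sizes removed by GPA.

    Every aligned configuration and the consensus have their centroid at the
    origin; configurations are scaled to unit centroid size, with the
    original centroid sizes kept in ``centroid_sizes``.
    """

    coords: np.ndarray                   # (n, k, 3) superimposed
    centroid_sizes: np.ndarray           # (n,) original CS, µm
    mean_shape: np.ndarray               # (k, 3) consensus
    specimens: list[str]
    species: list[str]
    groups: list[str] | None = None

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to ``(n, 3k)`` shape variables."""
        return self.coords.reshape(self.n_specimens, -1)

    def with_groups(self, groups: dict[str, str] | list[str]) -> "AlignedShapes":
        if isinstance(groups, dict):
            missing = [s for s in self.species if s not in groups]
            if missing:
                raise KeyError(f"group map missing species: {missing}")
            glist = [groups[s] for s in self.species]
        else:
            if len(groups) != self.n_specimens:
                raise ValueError("groups length does not match specimens")
            glist = list(groups)
        return replace(self, groups=glist)


@dataclass
class ShapeSpace:
    """Principal-component ordination of aligned shapes."""

    scores: np.ndarray            # (n, n_components)
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: np.ndarray          # (3k, n_components)
    specimens: list[str]
    mean: np.ndarray              # (3k,) centring vector


# --------------------------------------------------------------------------
# basic operations
# --------------------------------------------------------------------------

def average_replicates(sessions: list[LandmarkSet]) -> LandmarkSet:
    """Average repeated digitisation sessions landmark-wise.

    Replicate landmarking sessions of the same specimens are combined by the
    coordinate-wise arithmetic mean, the standard treatment of digitisation
    measurement error before analysis.
    """
    if not sessions:
        raise ValueError("no sessions given")
    ref = sessions[0]
    offenders = []
    for i, s in enumerate(sessions[1:], start=2):
        if s.specimens != ref.specimens:
            offenders.append(f"session {i}: specimen ids differ")
        if s.coords.shape != ref.coords.shape:
            offenders.append(f"session {i}: landmark array shape differs")
    if offenders:
        raise ValueError("sessions are not index-compatible: " + "; ".join(offenders))
    mean = np.mean([s.coords for s in sessions], axis=0)
    return LandmarkSet(mean, list(ref.specimens), list(ref.species),
                       {k: v.copy() for k, v in ref.subsets.items()})


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Invariant to translation and rotation; scales linearly under uniform
    scaling; zero iff all landmarks coincide.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 1:
        raise ValueError("configuration must be a non-empty (k, d) array")
    centred = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centred ** 2)))


def _optimal_rotation(source: np.ndarray, target: np.ndarray,
                      allow_reflection: bool = False) -> np.ndarray:
    """Rotation R minimising ||source @ R - target||_F (Kabsch/SVD)."""
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


def gpa(landmarks: LandmarkSet, subset: str = "all", *,
        tol: float = 1e-10, max_iter: int = 100,
        allow_reflection: bool = False) -> AlignedShapes:
    """Generalized Procrustes Analysis of a landmark subset.

    Each configuration is centred and scaled to unit centroid size, then
    iteratively rotated onto the running consensus until the consensus
    root-mean-square change falls below ``tol``.  Original centroid sizes
    are retained so that allometry (shape on size) can be studied after
    superimposition.  Reflections are excluded from the fitted rotations by
    default, preserving landmark homology.
    """
    lm = landmarks.subset(subset) if subset != "all" else landmarks
    X = lm.coords.copy()
    n, k, _ = X.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 specimens")

    sizes = np.empty(n)
    for i in range(n):
        X[i] -= X[i].mean(axis=0)
        cs = np.sqrt(np.sum(X[i] ** 2))
        if cs <= 0:
            raise ValueError(
                f"specimen {lm.specimens[i]!r} has all landmarks coincident")
        sizes[i] = cs
        X[i] /= cs

    # seed the consensus with the mean configuration: on already-aligned
    # input the first rotation pass is then the identity, making GPA a
    # fixed point of itself; fall back to the first specimen only if the
    # orientations cancel almost exactly
    consensus = X.mean(axis=0)
    norm = np.sqrt(np.sum(consensus ** 2))
    if norm < 1e-6:
        consensus = X[0].copy()
        norm = 1.0
    consensus = consensus / norm
    for _ in range(max_iter):
        for i in range(n):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus, allow_reflection)
        new = X.mean(axis=0)
        new -= new.mean(axis=0)
        norm = np.sqrt(np.sum(new ** 2))
        if norm <= 0:
            raise ValueError("degenerate consensus during GPA")
        new /= norm
        change = np.sqrt(np.mean((new - consensus) ** 2))
        consensus = new
        if change < tol:
            break

    return AlignedShapes(X, sizes, consensus, list(lm.specimens),
                         list(lm.species))


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two superimposed configurations."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"configuration shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


# --------------------------------------------------------------------------
# ordination
# --------------------------------------------------------------------------

def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Sign convention: the largest-magnitude loading of each axis is positive."""
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1


def shape_pca(shapes: AlignedShapes) -> ShapeSpace:
    """PCA of the specimen covariance of flattened aligned coordinates."""
    n = shapes.n_specimens
    if n < 3:
        raise ValueError("shape PCA needs at least 3 specimens")
    Y = shapes.flat()
    mean = Y.mean(axis=0)
    Yc = Y - mean
    # SVD of the centred data == eigendecomposition of the covariance
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    keep = eig > max(eig[0], 1.0) * 1e-12 if eig.size else slice(0)
    eig = eig[keep]
    scores = (U * s)[:, keep]
    loadings = Vt[keep].T
    _fix_signs(loadings, scores)
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    return ShapeSpace(scores, eig, pct, loadings, list(shapes.specimens), mean)


def between_group_pca(shapes: AlignedShapes,
                      groups: dict[str, str] | list[str] | None = None) -> ShapeSpace:
    """PCA on the covariance of group mean shapes, all specimens projected.

    With g groups the means span at most g-1 dimensions, so at most g-1
    non-null axes are returned; projecting every specimen onto these axes
    gives the between-group ordination used to display group separation.
    """
    if groups is not None:
        shapes = shapes.with_groups(groups)
    if shapes.groups is None:
        raise ValueError("no group labels available")
    labels = np.asarray(shapes.groups)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("between-group PCA needs at least 2 groups")
    Y = shapes.flat()
    means = np.stack([Y[labels == g].mean(axis=0) for g in uniq])
    grand = means.mean(axis=0)
    M = means - grand
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    eig = s ** 2 / max(len(uniq) - 1, 1)
    keep = eig > (eig[0] if eig.size and eig[0] > 0 else 1.0) * 1e-12
    eig = eig[keep]
    loadings = Vt[keep].T
    scores = (Y - grand) @ loadings
    _fix_signs(loadings, scores)
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    return ShapeSpace(scores, eig, pct, loadings, list(shapes.specimens), grand)


@dataclass
class ConfidenceEllipse:
    center: np.ndarray          # (2,)
    semi_axes: np.ndarray       # (2,) major, minor
    orientation: float          # radians of major axis vs first score axis
    coverage: float


def group_confidence_ellipse(scores: np.ndarray, members: np.ndarray,
                             *, coverage: float = 0.6827,
                             replicates: int = 5000,
                             seed: int | np.random.Generator | None = None,
                             axes: tuple[int, int] = (0, 1)) -> ConfidenceEllipse:
    """Bootstrap confidence ellipse for a group mean in a 2D score plane.

    The group's rows are resampled with replacement ``replicates`` times;
    the scatter of bootstrap means is summarised by its covariance and the
    ellipse drawn at the chi-square quantile of the requested coverage
    (0.6827 = the 1-sigma convention for bivariate normal scatter).
    """
    from scipy import stats

    pts = np.asarray(scores)[np.asarray(members)][:, list(axes)]
    m = pts.shape[0]
    if m < 3:
        raise ValueError("confidence ellipse needs a group of at least 3")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(replicates, m))
    boot_means = pts[idx].mean(axis=1)
    center = pts.mean(axis=0)
    cov = np.cov(boot_means.T)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    r2 = stats.chi2.ppf(coverage, df=2)
    semi = np.sqrt(evals * r2)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return ConfidenceEllipse(center, semi, angle, coverage)


def find_mean_spec(shapes: AlignedShapes) -> str:
    """Specimen closest to the consensus shape (ties broken by input order)."""
    if shapes.n_specimens < 1:
        raise ValueError("no specimens")
    d = [procrustes_distance(shapes.coords[i], shapes.mean_shape)
         for i in range(shapes.n_specimens)]
    return shapes.specimens[int(np.argmin(d))]


# --------------------------------------------------------------------------
# thin-plate-spline warping
# --------------------------------------------------------------------------

def _tps_system(source: np.ndarray) -> np.ndarray:
    k = source.shape[0]
    r = np.linalg.norm(source[:, None, :] - source[None, :, :], axis=2)
    K = r  # 3D biharmonic kernel U(r) = r
    P = np.hstack([np.ones((k, 1)), source])
    top = np.hstack([K, P])
    bottom = np.hstack([P.T, np.zeros((4, 4))])
    return np.vstack([top, bottom])


def tps_warp(source_landmarks: np.ndarray, target_landmarks: np.ndarray,
             vertices: np.ndarray) -> np.ndarray:
    """Thin-plate-spline map taking source landmarks exactly onto targets.

    Uses the 3D biharmonic kernel U(r) = r, so the interpolant is exact at
    the landmarks and reproduces affine maps (including pure translations)
    exactly.  ``vertices`` — e.g. a surface mesh registered to the source
    configuration — are carried along by the fitted spline.
    """
    src = np.asarray(source_landmarks, dtype=float)
    tgt = np.asarray(target_landmarks, dtype=float)
    V = np.atleast_2d(np.asarray(vertices, dtype=float))
    if src.shape != tgt.shape:
        raise ValueError("source and target landmark arrays differ in shape")
    k = src.shape[0]
    if k < 5:
        raise ValueError("3D TPS needs at least 5 landmarks")
    L = _tps_system(src)
    rhs = np.vstack([tgt, np.zeros((4, 3))])
    try:
        params = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular TPS system (coincident or coplanar source landmarks)"
        ) from exc
    W, A = params[:k], params[k:]
    r = np.linalg.norm(V[:, None, :] - src[None, :, :], axis=2)
    return r @ W + np.hstack([np.ones((V.shape[0], 1)), V]) @ A


def group_mean_deviation_map(shapes: AlignedShapes,
                             groups: dict[str, str] | list[str],
                             vertices: np.ndarray) -> dict[str, np.ndarray]:
    """Per-vertex displacement magnitude from overall mean to each group mean.

    The mesh (registered to the overall mean configuration) is TPS-warped
    from the consensus to each group's mean configuration; the field is the
    per-vertex Euclidean displacement, a heat-map of where that group's
    shape deviates from the grand mean.
    """
    shapes = shapes.with_groups(groups)
    labels = np.asarray(shapes.groups)
    V = np.asarray(vertices, dtype=float)
    out: dict[str, np.ndarray] = {}
    for g in sorted(set(labels)):
        gmean = shapes.coords[labels == g].mean(axis=0)
        warped = tps_warp(shapes.mean_shape, gmean, V)
        out[g] = np.linalg.norm(warped - V, axis=1)
    return out
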