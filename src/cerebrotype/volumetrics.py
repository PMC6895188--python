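"""Volume allometry of the cerebellum across locomotor modes.

On a log-log scale, cerebellar volume scales with whole-brain volume along
a regression line; locomotor groups may differ in intercept (grade shifts)
or slope (different allometries).  The analysis path is: fit per-mode PGLS
lines with Pagel's lambda estimated by maximum likelihood, test slope
homogeneity with a likelihood-ratio test, and — when slopes are
heterogeneous and the fitted phylogenetic signal is negligible — use the
Johnson–Neyman procedure to delimit the covariate interval over which two
modes differ significantly.  A univariate phylogenetic ANOVA of the
cerebellum-to-brain volume ratio complements the line-based comparison.

Volumes are natural-logged throughout; the log base only shifts covariate
thresholds, not the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import AnovaResult, phylo_procrustes_anova
from .trees import PhyloTree

__all__ = [
    "VolumeTable",
    "AncovaFit",
    "JNRegion",
    "fit_pgls_lines",
    "slope_homogeneity_test",
    "johnson_neyman",
    "ratio_anova",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class VolumeTable:
    """Per-species whole-brain and cerebellum volumes (mm^3) with mode labels."""

    species: list[str]
    brain_volume: np.ndarray
    cerebellum_volume: np.ndarray
    mode: list[str]

    def __post_init__(self) -> None:
        self.brain_volume = np.asarray(self.brain_volume, dtype=float)
        self.cerebellum_volume = np.asarray(self.cerebellum_volume, dtype=float)
        n = len(self.species)
        if not (len(self.mode) == n == self.brain_volume.size
                == self.cerebellum_volume.size):
            raise ValueError("volume table columns have unequal lengths")
        if np.any(self.brain_volume <= 0) or np.any(self.cerebellum_volume <= 0):
            raise ValueError("volumes must be strictly positive")
        bad = np.asarray(self.species)[self.cerebellum_volume
                                       >= self.brain_volume]
        if bad.size:
            raise ValueError(
                f"cerebellum volume >= brain volume for: {bad.tolist()}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       modes: dict[str, str] | None = None) -> "VolumeTable":
        mode = (df["mode"].tolist() if "mode" in df
                else [modes[s] for s in df["species"]])
        return cls(df["species"].tolist(), df["brain_mm3"].to_numpy(),
                   df["cerebellum_mm3"].to_numpy(), mode)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species,
            "brain_mm3": self.brain_volume,
            "cerebellum_mm3": self.cerebellum_volume,
            "mode": self.mode,
        })

    @property
    def log_brain(self) -> np.ndarray:
        return np.log(self.brain_volume)

    @property
    def log_cerebellum(self) -> np.ndarray:
        return np.log(self.cerebellum_volume)

    @property
    def ratio_pct(self) -> np.ndarray:
        """Cerebellum-to-whole-brain volume ratio in percent."""
        return 100.0 * self.cerebellum_volume / self.brain_volume


@dataclass
class AncovaFit:
    """Per-mode log-log regression lines fitted by PGLS with Pagel's lambda.

    ``coefficients`` are ordered [intercept(mode_1..mode_k), slope(mode_1..
    mode_k)] in ``modes`` order (separate-slopes model) or [intercepts...,
    common slope] when fitted with a shared slope.
    """

    modes: list[str]
    intercepts: dict[str, float]
    slopes: dict[str, float]
    coefficients: np.ndarray
    coef_covariance: np.ndarray
    lam: float
    sigma2: float
    loglik: float
    df_resid: int
    n: int
    x_range: tuple[float, float]
    interaction_p: float | None = None
    separate_slopes: bool = True
    coef_names: list[str] = field(default_factory=list)

    def line(self, mode: str, x: np.ndarray) -> np.ndarray:
        return self.intercepts[mode] + self.slopes[mode] * np.asarray(x)

    def confidence_band(self, mode: str, x: np.ndarray,
                        level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise CI of the fitted line from the coefficient covariance."""
        x = np.asarray(x, dtype=float)
        ia = self.coef_names.index(f"intercept[{mode}]")
        if self.separate_slopes:
            ib = self.coef_names.index(f"slope[{mode}]")
        else:
            ib = self.coef_names.index("slope")
        V = self.coef_covariance
        var = V[ia, ia] + 2 * x * V[ia, ib] + x ** 2 * V[ib, ib]
        t = stats.t.ppf(0.5 + level / 2, self.df_resid)
        mid = self.line(mode, x)
        half = t * np.sqrt(var)
        return mid - half, mid + half

    def summary(self) -> str:
        lines = [f"PGLS ANCOVA fit (lambda = {self.lam:.3f}, "
                 f"n = {self.n}, logLik = {self.loglik:.2f})"]
        for m in self.modes:
            lines.append(f"  {m}: log(cb) = {self.intercepts[m]:.3f} "
                         f"+ {self.slopes[m]:.3f} * log(brain)")
        if self.interaction_p is not None:
            lines.append(f"  slope homogeneity p = {self.interaction_p:.4g}")
        return "\n".join(lines)


@dataclass
class JNRegion:
    """Johnson–Neyman region of significance for one pair of modes."""

    pair: tuple[str, str]
    alpha: float
    intervals: list[tuple[float, float]]
    directions: list[str]          # which mode of the pair is higher
    observed_range: tuple[float, float]
    extrapolated: bool = False
    df: int = 0

    @property
    def empty(self) -> bool:
        return not self.intervals

    def summary(self) -> str:
        if self.empty:
            return (f"JN {self.pair[0]} vs {self.pair[1]}: no significant "
                    f"region at alpha = {self.alpha}")
        segs = ", ".join(f"[{a:.3f}, {b:.3f}] ({d} higher)"
                         for (a, b), d in zip(self.intervals, self.directions))
        return (f"JN {self.pair[0]} vs {self.pair[1]} (alpha = {self.alpha}, "
                f"df = {self.df}): {segs}")


# --------------------------------------------------------------------------
# PGLS with Pagel's lambda
# --------------------------------------------------------------------------

def _pagel_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls_profile(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """GLS fit with profiled variance; returns (beta, XtVinvX_inv, sigma2, ll)."""
    n = len(y)
    cho = np.linalg.cholesky(V)
    Xw = np.linalg.solve(cho, X)
    yw = np.linalg.solve(cho, y)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    e = yw - Xw @ beta
    sigma2 = float(e @ e) / n
    logdet = 2.0 * np.sum(np.log(np.diag(cho)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return beta, np.linalg.inv(XtX), sigma2, ll


def _fit_lambda(X: np.ndarray, y: np.ndarray, C: np.ndarray,
                lam: float | None = None):
    """ML fit of the Pagel-lambda phylogenetic linear model.

    lambda rescales the off-diagonal of C (0 = star tree / OLS, 1 = full
    Brownian structure); it is profiled out by bounded scalar ML.
    """
    if lam is not None:
        beta, XtXi, s2, ll = _gls_profile(X, y, _pagel_cov(C, lam))
        return beta, XtXi, s2, ll, lam

    def nll(l: float) -> float:
        return -_gls_profile(X, y, _pagel_cov(C, l))[3]

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam_hat = float(res.x)
    # the bounded optimum can sit at an edge; compare against both edges
    for edge in (0.0, 1.0):
        if nll(edge) < nll(lam_hat):
            lam_hat = edge
    beta, XtXi, s2, ll = _gls_profile(X, y, _pagel_cov(C, lam_hat))
    return beta, XtXi, s2, ll, lam_hat


def _design(volumes: VolumeTable, separate_slopes: bool):
    modes = sorted(set(volumes.mode))
    g = np.asarray(volumes.mode)
    x = volumes.log_brain
    G = np.stack([(g == m).astype(float) for m in modes], axis=1)
    names = [f"intercept[{m}]" for m in modes]
    if separate_slopes:
        X = np.hstack([G, G * x[:, None]])
        names += [f"slope[{m}]" for m in modes]
    else:
        X = np.hstack([G, x[:, None]])
        names += ["slope"]
    return X, modes, names


def fit_pgls_lines(volumes: VolumeTable, tree: PhyloTree, *,
                   separate_slopes: bool = True,
                   lam: float | None = None) -> AncovaFit:
    """Fit per-mode log-log allometric lines by PGLS with Pagel's lambda.

    The residual covariance is sigma^2 (lambda*C + (1-lambda)*diag(C));
    lambda is estimated by ML unless fixed.  Coefficient covariance uses
    the unbiased residual variance (n - q denominator).
    """
    counts = pd.Series(volumes.mode).value_counts()
    thin = counts[counts < 3]
    if len(thin):
        raise ValueError(
            f"fewer than 3 species for mode(s): {thin.index.tolist()}")
    y = volumes.log_cerebellum
    C = tree.covariance(volumes.species, prune_extra=True)
    X, modes, names = _design(volumes, separate_slopes)
    n, q = X.shape
    beta, XtXi, s2_ml, ll, lam_hat = _fit_lambda(X, y, C, lam)
    s2 = s2_ml * n / (n - q)
    cov = s2 * XtXi
    k = len(modes)
    intercepts = {m: float(beta[i]) for i, m in enumerate(modes)}
    if separate_slopes:
        slopes = {m: float(beta[k + i]) for i, m in enumerate(modes)}
    else:
        slopes = {m: float(beta[k]) for m in modes}
    return AncovaFit(modes, intercepts, slopes, beta, cov, lam_hat, s2, ll,
                     n - q, n, (float(volumes.log_brain.min()),
                                float(volumes.log_brain.max())),
                     separate_slopes=separate_slopes, coef_names=names)


def slope_homogeneity_test(volumes: VolumeTable, tree: PhyloTree,
                           ) -> tuple[float, AncovaFit]:
    """Likelihood-ratio test of the mode-by-covariate interaction.

    Compares the separate-slopes phylogenetic model against the common-
    slope one (each with its own ML lambda); 2*deltaLL ~ chi^2 with k-1
    degrees of freedom.  A small p rejects the slope-homogeneity assumption
    of conventional ANCOVA, gating the Johnson–Neyman branch.
    """
    full = fit_pgls_lines(volumes, tree, separate_slopes=True)
    red = fit_pgls_lines(volumes, tree, separate_slopes=False)
    k = len(full.modes)
    if k < 2:
        raise ValueError("slope homogeneity needs at least 2 modes")
    lr = max(2.0 * (full.loglik - red.loglik), 0.0)
    p = float(stats.chi2.sf(lr, df=k - 1))
    full.interaction_p = p
    return p, full


# --------------------------------------------------------------------------
# Johnson–Neyman
# --------------------------------------------------------------------------

def johnson_neyman(fit: AncovaFit, pair: tuple[str, str], *,
                   alpha: float = 0.05,
                   x_range: tuple[float, float] | None = None,
                   df: int | None = None) -> JNRegion:
    """Johnson–Neyman region of significance for two regression lines.

    With d(x) the between-line difference and v(x) its variance from the
    coefficient covariance, the region is {x : d(x)^2 / v(x) >= t^2}; its
    boundaries are the real roots of the quadratic
    (db^2 - t^2 Vbb) x^2 + 2 (db*da - t^2 Vab) x + (da^2 - t^2 Vaa) = 0,
    where da, db are the intercept and slope differences.  Intervals are
    reported intersected with the observed covariate range; degenerate
    (linear or constant) cases fall back to sign analysis.  Default df is
    n - 4: two lines with two parameters each.
    """
    if not fit.separate_slopes:
        raise ValueError("Johnson–Neyman requires a separate-slopes fit")
    a_m, b_m = pair
    for m in pair:
        if m not in fit.modes:
            raise KeyError(f"mode {m!r} not in fit")
    if x_range is None:
        x_range = fit.x_range
    if df is None:
        df = fit.n - 4
    t2 = float(stats.t.ppf(1 - alpha / 2, df) ** 2)

    names = fit.coef_names
    ia1, ia2 = names.index(f"intercept[{a_m}]"), names.index(f"intercept[{b_m}]")
    ib1, ib2 = names.index(f"slope[{a_m}]"), names.index(f"slope[{b_m}]")
    da = fit.coefficients[ia1] - fit.coefficients[ia2]
    db = fit.coefficients[ib1] - fit.coefficients[ib2]
    V = fit.coef_covariance
    c_int = np.zeros(len(names)); c_int[ia1], c_int[ia2] = 1, -1
    c_slp = np.zeros(len(names)); c_slp[ib1], c_slp[ib2] = 1, -1
    Vaa = float(c_int @ V @ c_int)
    Vbb = float(c_slp @ V @ c_slp)
    Vab = float(c_int @ V @ c_slp)

    A = db ** 2 - t2 * Vbb
    B = 2 * (db * da - t2 * Vab)
    Cq = da ** 2 - t2 * Vaa

    # q(x) >= 0 <=> the pair differs significantly at x
    def q(x: float) -> float:
        return A * x * x + B * x + Cq

    lo, hi = x_range
    segments: list[tuple[float, float]] = []
    scale = max(abs(A), abs(B), abs(Cq), 1e-300)
    if abs(A) > 1e-12 * scale:
        disc = B * B - 4 * A * Cq
        if disc < 0:
            roots: list[float] = []
        else:
            r = np.sqrt(disc)
            roots = sorted([(-B - r) / (2 * A), (-B + r) / (2 * A)])
        if not roots:
            if A > 0:
                segments = [(lo, hi)]
        elif A > 0:
            # significant outside the roots
            segments = [(lo, min(roots[0], hi)), (max(roots[1], lo), hi)]
        else:
            # significant between the roots
            segments = [(max(roots[0], lo), min(roots[1], hi))]
    elif abs(B) > 1e-12 * scale:
        x0 = -Cq / B
        segments = [(lo, min(x0, hi))] if B < 0 else [(max(x0, lo), hi)]
    else:
        segments = [(lo, hi)] if Cq >= 0 else []

    intervals, directions = [], []
    for a, b in segments:
        a, b = max(a, lo), min(b, hi)
        if b - a > 1e-12:
            mid = 0.5 * (a + b)
            d_mid = da + db * mid
            intervals.append((float(a), float(b)))
            directions.append(a_m if d_mid > 0 else b_m)
    return JNRegion(pair, alpha, intervals, directions, (lo, hi), df=df)


# --------------------------------------------------------------------------
# ratio ANOVA
# --------------------------------------------------------------------------

def ratio_anova(volumes: VolumeTable, tree: PhyloTree, *,
                permutations: int = 1000,
                seed: int | np.random.Generator | None = None) -> AnovaResult:
    """Phylogenetic ANOVA of the cerebellum-to-brain volume ratio (%).

    Univariate D-PGLS of the percentage ratio on locomotor mode, with the
    same RRPP machinery and pairwise post hoc tests as the shape ANOVA.
    """
    y = volumes.ratio_pct[:, None]
    res = phylo_procrustes_anova(y, list(volumes.mode), tree,
                                 species=volumes.species,
                                 permutations=permutations, seed=seed)
    res.term = "ANOVA (volume ratio %)"
    return res
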