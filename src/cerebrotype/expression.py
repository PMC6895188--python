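"""Downstream comparative transcriptomics of ortholog expression matrices.

Input is a genes-by-species matrix of FPKM values for one-to-one orthologs.
The analysis chain: drop genes never expressed above a noise threshold;
z-score gene rows for heat-map clustering; agglomerative clustering of
genes (expression archetypes) and of species (expression phylogeny) under
Euclidean or correlation distances; node support by multiscale bootstrap
resampling of genes with approximately-unbiased (AU) p-values; and
hypergeometric GO-term enrichment of gene clusters with Benjamini-Hochberg
correction.

The scientific question the species dendrogram answers: do species group
by their phylogeny or by their locomotor mode?  Mode-dominated grouping of
the expression profiles indicates ecology-driven expression evolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionMatrix",
    "ClusterResult",
    "EnrichmentResult",
    "filter_orthologs",
    "zscore_rows",
    "hierarchical_cluster",
    "pairwise_correlation",
    "au_from_bp",
    "multiscale_bootstrap_au",
    "go_enrichment",
]

log = logging.getLogger(__name__)

_METRICS = ("euclidean", "pearson", "spearman")


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x species FPKM matrix with optional locomotor-mode labels."""

    values: pd.DataFrame                     # index = genes, columns = species
    modes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 species")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def species(self) -> list[str]:
        return self.values.columns.tolist()

    @classmethod
    def from_tsv(cls, path: str, modes: dict[str, str] | None = None
                 ) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), modes)

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class ClusterResult:
    """Dendrogram with optional flat cut and bootstrap support per node."""

    linkage: np.ndarray
    labels: list[str]
    axis: str                                  # "genes" or "species"
    metric: str
    cluster_labels: dict[str, int] | None = None
    au: dict[frozenset, float] | None = None   # % per internal-node tip set
    bp: dict[frozenset, float] | None = None
    au_flags: dict[frozenset, str] = field(default_factory=dict)

    def clades(self) -> list[frozenset]:
        """Tip-label sets of all non-trivial internal nodes."""
        return _clades_of(self.linkage, self.labels)

    def summary(self) -> str:
        lines = [f"Hierarchical clustering of {self.axis} "
                 f"({self.metric} distance, {len(self.labels)} items)"]
        if self.cluster_labels is not None:
            k = len(set(self.cluster_labels.values()))
            lines.append(f"  flat cut into {k} clusters")
        if self.au is not None:
            lines.append("  node support (AU% / BP%):")
            for clade in sorted(self.au, key=len):
                au = self.au[clade]
                bp = self.bp[clade] if self.bp else float("nan")
                names = ",".join(sorted(clade))
                lines.append(f"    {{{names}}}: {au:.1f} / {bp:.1f}")
        return "\n".join(lines)


@dataclass
class EnrichmentResult:
    """One GO term's enrichment in a gene cluster."""

    go_id: str
    term: str
    k: int            # cluster genes with the term
    K: int            # background genes with the term
    n: int            # cluster size
    N: int            # background size
    p: float
    p_adjusted: float

    def as_dict(self) -> dict:
        return {"go_id": self.go_id, "term": self.term, "k": self.k,
                "K": self.K, "n": self.n, "N": self.N, "p": self.p,
                "p_adjusted": self.p_adjusted}


# --------------------------------------------------------------------------
# filtering and scaling
# --------------------------------------------------------------------------

def filter_orthologs(matrix: ExpressionMatrix,
                     threshold: float = 0.5) -> ExpressionMatrix:
    """Keep genes expressed strictly above *threshold* FPKM in >= 1 species.

    The boundary is exclusive: a gene whose maximum equals the threshold is
    removed (strictly "above").
    """
    keep = matrix.values.max(axis=1) > threshold
    if not keep.any():
        raise ValueError(
            f"no genes exceed {threshold} FPKM in any species; "
            "lower the threshold")
    dropped = int((~keep).sum())
    if dropped:
        log.info("filtered %d/%d genes at %.3g FPKM", dropped,
                 len(keep), threshold)
    return ExpressionMatrix(matrix.values.loc[keep], matrix.modes)


def zscore_rows(matrix: ExpressionMatrix | pd.DataFrame
                ) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each gene row; constant rows become all-zero and are flagged."""
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("need at least 2 species to scale")
    vals = df.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd.ravel() == 0)
    sd[flat[:, None]] = 1.0
    z = (vals - mean) / sd
    z[flat] = 0.0
    flagged = df.index[flat].tolist()
    if flagged:
        log.info("constant expression rows set to zero: %d genes", len(flagged))
    return pd.DataFrame(z, index=df.index, columns=df.columns), flagged


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def _distance(data: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance vector between rows of *data*."""
    if metric == "euclidean":
        from scipy.spatial.distance import pdist
        return pdist(data, metric="euclidean")
    if metric == "pearson":
        r = np.corrcoef(data)
    elif metric == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 1, data)
        r = np.corrcoef(ranks)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    np.fill_diagonal(r, 1.0)
    return squareform(1.0 - r, checks=False)


def _clades_of(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = len(labels)
    sets: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for row_i, (a, b, _, _) in enumerate(Z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + row_i] = s
        if 1 < len(s) < n:
            out.append(s)
    return out


def hierarchical_cluster(data, *, axis: str = "genes",
                         metric: str = "euclidean",
                         linkage: str = "average",
                         k: int | None = None) -> ClusterResult:
    """Agglomerative clustering of genes or species.

    ``metric`` is Euclidean distance or 1 - Pearson / 1 - Spearman
    correlation between rows of the clustered axis.  A flat cut into ``k``
    clusters (the archetype analysis uses k = 3) is optional.
    """
    if isinstance(data, ExpressionMatrix):
        df = data.values
    else:
        df = data
    mat = df.to_numpy(dtype=float)
    if axis == "species":
        mat = mat.T
        labels = list(df.columns)
    elif axis == "genes":
        labels = list(df.index)
    else:
        raise ValueError("axis must be 'genes' or 'species'")
    if len(labels) < 3:
        raise ValueError("need at least 3 items to cluster")
    d = _distance(mat, metric)
    Z = hierarchy.linkage(d, method=linkage)
    cluster_labels = None
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        cluster_labels = {lab: int(c) for lab, c in zip(labels, flat)}
    return ClusterResult(Z, labels, axis, metric, cluster_labels)


def pairwise_correlation(matrix: ExpressionMatrix | pd.DataFrame
                         ) -> pd.DataFrame:
    """Species-by-species Pearson correlation of expression profiles."""
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    vals = df.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    bad = df.columns[sd == 0].tolist()
    if bad:
        raise ValueError(f"constant expression column(s): {bad}; "
                         "correlation undefined")
    r = np.corrcoef(vals.T)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=df.columns, columns=df.columns)


# --------------------------------------------------------------------------
# multiscale bootstrap AU support
# --------------------------------------------------------------------------

def au_from_bp(bp: np.ndarray, scales: np.ndarray,
               iterations: int) -> tuple[float, str | None]:
    """AU percentage from per-scale bootstrap proportions.

    Fits z(r) = v*sqrt(r) + c/sqrt(r), z = Phi^-1(1 - BP(r)), by weighted
    least squares (delta-method binomial weights) and extrapolates to
    AU = 1 - Phi(v - c).  Returns (AU %, flag-or-None).
    """
    bp = np.asarray(bp, dtype=float)
    scales = np.asarray(scales, dtype=float)
    eps = 1.0 / (2.0 * iterations)
    # only scales where the proportion is informative constrain the fit;
    # all-0 / all-1 profiles pin z at the clipping value and make the two
    # basis functions indistinguishable, so they are resolved by the
    # eps-capped limit instead
    use = (bp > 0.0) & (bp < 1.0)
    if use.sum() < 2:
        if bp.mean() >= 0.5:
            return 100.0 * (1.0 - eps), "uniform bootstrap profile (high)"
        return 100.0 * eps, "uniform bootstrap profile (low)"
    b = np.clip(bp[use], eps, 1 - eps)
    z = stats.norm.ppf(1.0 - b)
    w = iterations * stats.norm.pdf(z) ** 2 / (b * (1 - b))
    sq = np.sqrt(scales[use])
    X = np.column_stack([sq, 1.0 / sq])
    Wx = X * w[:, None]
    try:
        v, c = np.linalg.solve(X.T @ Wx, Wx.T @ z)
    except np.linalg.LinAlgError:
        return (float(np.clip(100.0 * (1 - b.mean()), 0, 100)),
                "degenerate extrapolation; raw BP reported")
    au = float(np.clip(100.0 * (1.0 - stats.norm.cdf(v - c)), 0.0, 100.0))
    return au, None


def multiscale_bootstrap_au(matrix: ExpressionMatrix | pd.DataFrame, *,
                            metric: str = "pearson",
                            linkage: str = "average",
                            scales: np.ndarray | None = None,
                            iterations: int = 1000,
                            seed: int | np.random.Generator | None = None,
                            ) -> ClusterResult:
    """Species dendrogram with AU/BP support from multiscale bootstrap.

    Genes are resampled with replacement at a ladder of sample-size scales
    r (default 0.5..1.4 in steps of 0.1, round(r*n_genes) genes per
    replicate); per internal node, BP(r) is the fraction of replicate
    dendrograms containing the identical tip set.  The AU value
    extrapolates to r -> the "observed data" limit by fitting
    z(r) = v*sqrt(r) + c/sqrt(r) with z = Phi^-1(1 - BP) by weighted least
    squares, giving AU = 1 - Phi(v - c).  BP values of exactly 0 or 1 are
    shifted by eps = 1/(2*iterations) before the probit; a node never seen
    at any scale gets AU = 0 with a flag.  Reported values are percentages.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if scales is None:
        scales = np.arange(0.5, 1.41, 0.1)
    scales = np.asarray(scales, dtype=float)
    vals = df.to_numpy(dtype=float)
    n_genes, n_species = vals.shape

    base = hierarchical_cluster(df, axis="species", metric=metric,
                                linkage=linkage)
    clades = base.clades()
    rng = np.random.default_rng(seed)

    counts = np.zeros((len(scales), len(clades)))
    clade_index = {c: j for j, c in enumerate(clades)}
    labels = base.labels
    for si, r in enumerate(scales):
        m = max(int(round(r * n_genes)), 2)
        for _ in range(iterations):
            idx = rng.integers(0, n_genes, size=m)
            sub = vals[idx]
            sd = sub.std(axis=0)
            if metric != "euclidean" and np.any(sd == 0):
                sub = sub + 1e-9 * rng.standard_normal(sub.shape)
            d = _distance(sub.T, metric)
            Z = hierarchy.linkage(d, method=linkage)
            for c in _clades_of(Z, labels):
                j = clade_index.get(c)
                if j is not None:
                    counts[si, j] += 1

    bp = counts / iterations
    au_map: dict[frozenset, float] = {}
    bp_map: dict[frozenset, float] = {}
    flags: dict[frozenset, str] = {}
    scale1 = int(np.argmin(np.abs(scales - 1.0)))
    for c, j in clade_index.items():
        bp_map[c] = 100.0 * bp[scale1, j]
        if counts[:, j].sum() == 0:
            au_map[c] = 0.0
            flags[c] = "never recovered at any scale"
            continue
        au, flag = au_from_bp(bp[:, j], scales, iterations)
        au_map[c] = au
        if flag:
            flags[c] = flag
    base.au, base.bp, base.au_flags = au_map, bp_map, flags
    return base


# --------------------------------------------------------------------------
# GO enrichment
# --------------------------------------------------------------------------

def go_enrichment(gene_set: list[str],
                  annotation: pd.DataFrame | dict[str, list[tuple[str, str]]],
                  background: list[str], *,
                  p_threshold: float = 0.01,
                  min_genes: int = 10,
                  report_all: bool = False) -> list[EnrichmentResult]:
    """Hypergeometric GO-term enrichment of a gene cluster.

    For each term with K background annotations, the upper-tail
    hypergeometric probability P(X >= k) of observing k annotated genes in
    a cluster of n drawn from a background of N.  Benjamini-Hochberg
    adjustment is applied across all tested terms; by default only terms
    with raw p < ``p_threshold`` and at least ``min_genes`` cluster genes
    are reported (set ``report_all`` to get every tested term).
    """
    bg = set(background)
    gs = set(gene_set)
    if not gs <= bg:
        raise ValueError("gene_set must be a subset of background")
    if isinstance(annotation, pd.DataFrame):
        ann_iter = annotation[["gene", "go_id", "term"]].itertuples(index=False)
    else:
        ann_iter = ((g, go, term) for g, pairs in annotation.items()
                    for go, term in pairs)
    term_genes: dict[str, set] = {}
    term_names: dict[str, str] = {}
    for gene, go_id, term in ann_iter:
        if gene not in bg:
            log.debug("annotation for gene outside background skipped: %s", gene)
            continue
        term_genes.setdefault(go_id, set()).add(gene)
        term_names[go_id] = term

    N, n = len(bg), len(gs)
    rows = []
    for go_id, genes in sorted(term_genes.items()):
        K = len(genes)
        k = len(genes & gs)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append((go_id, term_names[go_id], k, K, p))
    if not rows:
        return []
    praw = np.array([r[4] for r in rows])
    padj = stats.false_discovery_control(praw, method="bh")
    out = []
    for (go_id, name, k, K, p), q in zip(rows, padj):
        res = EnrichmentResult(go_id, name, k, K, n, N, p, float(q))
        if report_all or (p < p_threshold and k >= min_genes):
            out.append(res)
    out.sort(key=lambda r: r.p)
    return out
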