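"""Purkinje-cell scattering across the cerebellar molecular layer.

Purkinje-cell somata sit either in an ordered monolayer just above the
granule cell layer (GCL) or scattered through the molecular layer (ML),
depending on species.  Each labelled cell contributes one observation: its
distance to the inner GCL border, normalised by the local ML thickness to
a depth percentage (0% = GCL border, 100% = pial surface).  Species are
compared with the Kruskal–Wallis rank test (depth distributions are far
from normal) followed by the Dwass–Steel–Critchlow–Fligner (DSCF) pairwise
post hoc, and partitioned into positioning patterns — ordered monolayer
through totally scattered — from the graph of statistically
indistinguishable species pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellDepthTable",
    "ScatterGroups",
    "normalize_depths",
    "kruskal_wallis",
    "dscf_posthoc",
    "partition_patterns",
]

log = logging.getLogger(__name__)

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]


# --------------------------------------------------------------------------
# container
# --------------------------------------------------------------------------

@dataclass
class CellDepthTable:
    """Per-cell (distance to GCL, local ML thickness) records, in µm."""

    species: list[str]
    cell_id: list[str]
    dist_gcl: np.ndarray
    ml_thickness: np.ndarray

    def __post_init__(self) -> None:
        self.dist_gcl = np.asarray(self.dist_gcl, dtype=float)
        self.ml_thickness = np.asarray(self.ml_thickness, dtype=float)
        n = len(self.species)
        if not (len(self.cell_id) == n == self.dist_gcl.size
                == self.ml_thickness.size):
            raise ValueError("cell depth table columns have unequal lengths")
        if np.any(self.dist_gcl < 0):
            raise ValueError("distances to GCL must be non-negative")
        if np.any(self.ml_thickness <= 0):
            raise ValueError("ML thickness must be strictly positive")
        counts = pd.Series(self.species).value_counts()
        outside = counts[(counts < 250) | (counts > 750)]
        if len(outside):
            warnings.warn(
                "cell counts outside the expected 250-750 per species: "
                f"{outside.to_dict()}", stacklevel=2)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CellDepthTable":
        return cls(df["species"].tolist(),
                   df["cell_id"].astype(str).tolist(),
                   df["dist_gcl_um"].to_numpy(),
                   df["ml_thickness_um"].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species,
            "cell_id": self.cell_id,
            "dist_gcl_um": self.dist_gcl,
            "ml_thickness_um": self.ml_thickness,
        })

    def depths_by_species(self) -> dict[str, np.ndarray]:
        pct = normalize_depths(self)
        sp = np.asarray(self.species)
        return {s: pct[sp == s] for s in dict.fromkeys(self.species)}


@dataclass
class ScatterGroups:
    """KW result, DSCF matrix, and the derived positioning patterns."""

    kw_H: float
    kw_p: float
    pairwise_p: pd.DataFrame
    patterns: dict[str, str]
    alpha: float
    transitive: bool
    confirmation_kw: tuple[float, float] | None = None

    def summary(self) -> str:
        lines = [f"Kruskal–Wallis: H = {self.kw_H:.3f}, p = {self.kw_p:.4g}"]
        by_pattern: dict[str, list[str]] = {}
        for sp, pat in self.patterns.items():
            by_pattern.setdefault(pat, []).append(sp)
        for pat in sorted(by_pattern):
            lines.append(f"  pattern {pat}: {', '.join(sorted(by_pattern[pat]))}")
        if self.confirmation_kw is not None:
            h, p = self.confirmation_kw
            lines.append(f"  between-pattern KW: H = {h:.3f}, p = {p:.4g}")
        if not self.transitive:
            lines.append("  note: non-significance graph is not transitive; "
                         "patterns are connected components")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def normalize_depths(table: CellDepthTable) -> np.ndarray:
    """Normalised depth: 100 * distance-to-GCL / local ML thickness.

    0% is a soma sitting on the GCL border, 100% one at the pial surface.
    """
    bad = np.nonzero(table.dist_gcl > table.ml_thickness)[0]
    if bad.size:
        ids = [table.cell_id[i] for i in bad[:20]]
        raise ValueError(
            f"{bad.size} cells with distance > ML thickness, e.g. {ids}")
    return 100.0 * table.dist_gcl / table.ml_thickness


def _kw_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal–Wallis H."""
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        H += r.sum() ** 2 / g.size
        start += g.size
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (N ** 3 - N)
    return H / tie if tie > 0 else 0.0


def _kw_exact_p(groups: list[np.ndarray], H_obs: float) -> float:
    """Exact permutation p for the KW statistic by full enumeration.

    Enumerates every assignment of the pooled observations to groups of
    the given sizes (feasible for N <= 10) and reports the fraction with
    H >= H_obs; the observed assignment is one of the enumerated ones, so
    no +1 correction is needed.
    """
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    N = pooled.size
    idx_all = frozenset(range(N))

    count = 0
    total = 0

    def rec(remaining: frozenset, chosen: list[list[int]]):
        nonlocal count, total
        if len(chosen) == len(sizes) - 1:
            parts = chosen + [sorted(remaining)]
            H = _kw_statistic([pooled[list(p)] for p in parts])
            total += 1
            if H >= H_obs - 1e-12:
                count += 1
            return
        k = len(chosen)
        for comb in combinations(sorted(remaining), sizes[k]):
            rec(remaining - set(comb), chosen + [list(comb)])

    rec(idx_all, [])
    return count / total


def kruskal_wallis(depths: dict[str, np.ndarray] | CellDepthTable, *,
                   exact_max_n: int = 10) -> tuple[float, float]:
    """Kruskal–Wallis test across species depth distributions.

    Rank-based with tie correction; p from the chi-square approximation
    (k-1 df), or by exact enumeration of group assignments when the pooled
    sample is small (N <= ``exact_max_n``).  All-identical data yields
    H = 0, p = 1 by convention.
    """
    if isinstance(depths, CellDepthTable):
        depths = depths.depths_by_species()
    groups = [np.asarray(v, dtype=float) for v in depths.values()]
    if len(groups) < 2:
        raise ValueError("Kruskal–Wallis needs at least 2 species")
    if any(g.size < 2 for g in groups):
        raise ValueError("every species needs at least 2 cells")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        log.info("all depth values identical; returning H=0, p=1")
        return 0.0, 1.0
    H = _kw_statistic(groups)
    if pooled.size <= exact_max_n:
        p = _kw_exact_p(groups, H)
    else:
        p = float(stats.chi2.sf(H, df=len(groups) - 1))
    return float(H), p


def dscf_posthoc(depths: dict[str, np.ndarray] | CellDepthTable, *,
                 exact_max_n: int = 10) -> pd.DataFrame:
    """Dwass–Steel–Critchlow–Fligner pairwise comparisons.

    For each species pair the two samples are jointly ranked; the
    tie-corrected standardised Wilcoxon rank-sum statistic W* is referred
    to the Studentized range distribution with k groups (p =
    P(q >= |W*| * sqrt(2)) at infinite df), controlling the family-wise
    error over all pairs.  When a pair's pooled sample is small
    (N <= ``exact_max_n``), where the asymptotic reference is unreliable,
    the two-sided p is computed instead by exhaustive enumeration of the
    rank-sum permutation distribution.  Returns a symmetric
    species-by-species p-value matrix.
    """
    if isinstance(depths, CellDepthTable):
        depths = depths.depths_by_species()
    names = list(depths.keys())
    k = len(names)
    if k < 2:
        raise ValueError("post hoc needs at least 2 species")
    P = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for a, b in combinations(range(k), 2):
        x = np.asarray(depths[names[a]], dtype=float)
        y = np.asarray(depths[names[b]], dtype=float)
        n1, n2 = x.size, y.size
        N = n1 + n2
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        W = ranks[n1:].sum()                       # rank sum of second sample
        mean = n2 * (N + 1) / 2.0
        if N <= exact_max_n:
            obs = abs(W - mean)
            hits = total = 0
            for iy in combinations(range(N), n2):
                w = abs(ranks[list(iy)].sum() - mean)
                total += 1
                hits += w >= obs - 1e-12
            p = hits / total
            P.iloc[a, b] = P.iloc[b, a] = p
            continue
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts * (counts - 1) * (counts + 1)) / (N - 1)
        var = n1 * n2 / 24.0 * (N + 1 - tie_term / N) * 2.0
        if var <= 0:
            p = 1.0
        else:
            z = (W - mean) / np.sqrt(var)
            p = float(stats.studentized_range.sf(abs(z) * np.sqrt(2.0),
                                                 k, np.inf))
        P.iloc[a, b] = P.iloc[b, a] = p
    return P


def partition_patterns(pairwise_p: pd.DataFrame,
                       depths: dict[str, np.ndarray] | CellDepthTable | None = None,
                       *, alpha: float = 0.05) -> ScatterGroups | dict[str, str]:
    """Partition species into positioning patterns from the DSCF matrix.

    Species pairs that are NOT significantly different (p >= alpha) are
    linked; patterns are the connected components of that graph — a
    deterministic, order-independent rule.  When the graph is not
    transitive (a component containing a significant pair) the result is
    flagged.  Patterns are labelled I, II, ... by ascending median depth;
    when depth data are given, a confirmation Kruskal–Wallis re-tests the
    derived patterns against each other and the full :class:`ScatterGroups`
    is returned (otherwise just the assignment map).
    """
    import networkx as nx

    names = list(pairwise_p.index)
    G = nx.Graph()
    G.add_nodes_from(names)
    for a, b in combinations(names, 2):
        if pairwise_p.loc[a, b] >= alpha:
            G.add_edge(a, b)
    components = [sorted(c) for c in nx.connected_components(G)]

    transitive = all(
        pairwise_p.loc[a, b] >= alpha
        for comp in components for a, b in combinations(comp, 2))
    if not transitive:
        log.warning("non-significance graph is not transitive; pattern "
                    "membership uses connected components")

    depth_map = None
    if depths is not None:
        depth_map = (depths.depths_by_species()
                     if isinstance(depths, CellDepthTable) else depths)

    def comp_key(comp: list[str]):
        if depth_map is None:
            return (comp[0],)
        return (float(np.median(np.concatenate(
            [np.asarray(depth_map[s], dtype=float) for s in comp]))),)

    components.sort(key=comp_key)
    assignment = {s: _ROMAN[i] for i, comp in enumerate(components)
                  for s in comp}

    if depth_map is None:
        return assignment

    kw_H, kw_p = kruskal_wallis(depth_map)
    confirmation = None
    if len(components) > 1:
        merged = {
            _ROMAN[i]: np.concatenate(
                [np.asarray(depth_map[s], dtype=float) for s in comp])
            for i, comp in enumerate(components)}
        confirmation = kruskal_wallis(merged)
    return ScatterGroups(kw_H, kw_p, pairwise_p, assignment, alpha,
                         transitive, confirmation)


def species_summary(table: CellDepthTable) -> pd.DataFrame:
    """Per-species median, IQR and cell count of normalised depth."""
    rows = []
    for sp, d in table.depths_by_species().items():
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        rows.append({"species": sp, "median_pct": med, "iqr_pct": q3 - q1,
                     "n_cells": d.size})
    return pd.DataFrame(rows)
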