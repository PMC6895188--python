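"""Rooted phylogenies with branch lengths and their Brownian-motion covariance.

A tree enters every comparative statistic in this package only through two
objects: the tip covariance matrix ``C`` (shared root-to-MRCA path lengths,
the covariance of tip values under Brownian motion) and, for ancestral-state
work, the edge list itself.  :class:`PhyloTree` wraps a dendropy tree and
caches an indexed edge representation so both are cheap to obtain repeatedly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["PhyloTree", "phylo_covariance"]


@dataclass
class _EdgeTable:
    """Flat, index-based view of a rooted tree.

    Nodes are numbered in preorder (root = 0).  ``parent[i]`` is the parent
    index (-1 for the root) and ``length[i]`` the length of the edge above
    node ``i`` (0 for the root).
    """

    parent: np.ndarray
    length: np.ndarray
    tip_index: dict[str, int]
    children: list[list[int]] = field(repr=False, default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def depths(self) -> np.ndarray:
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):  # preorder: parent before child
            d[i] = d[self.parent[i]] + self.length[i]
        return d


class PhyloTree:
    """A rooted tree with strictly positive branch lengths and labelled tips."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._edges: _EdgeTable | None = None

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        """Parse a Newick string or file path (branch lengths required)."""
        if "(" in source:
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has edges without branch lengths")
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ----------------------------------------------------------- properties
    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def edge_table(self) -> _EdgeTable:
        """Indexed preorder edge representation (cached)."""
        if self._edges is None:
            nodes = list(self._tree.preorder_node_iter())
            index = {id(nd): i for i, nd in enumerate(nodes)}
            parent = np.full(len(nodes), -1, dtype=int)
            length = np.zeros(len(nodes))
            children: list[list[int]] = [[] for _ in nodes]
            tips: dict[str, int] = {}
            for i, nd in enumerate(nodes):
                if nd.parent_node is not None:
                    p = index[id(nd.parent_node)]
                    parent[i] = p
                    children[p].append(i)
                    length[i] = float(nd.edge.length or 0.0)
                if nd.is_leaf():
                    tips[nd.taxon.label] = i
            self._edges = _EdgeTable(parent, length, tips, children)
        return self._edges

    # ---------------------------------------------------------- operations
    def prune_to(self, species: list[str]) -> "PhyloTree":
        """Return a copy restricted to *species* (order-insensitive)."""
        keep = set(species)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        return PhyloTree(clone)

    def covariance(self, species: list[str] | None = None,
                   prune_extra: bool = False) -> np.ndarray:
        """Brownian-motion tip covariance ``C`` in the given species order.

        ``C[i, j]`` is the root-to-MRCA path length of tips i and j; the
        diagonal holds root-to-tip depths.  Missing species raise; extra
        tips in the tree raise unless ``prune_extra``.
        """
        tips = self.tip_labels
        if species is None:
            species = tips
        missing = set(species) - set(tips)
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        if set(tips) - set(species):
            if not prune_extra:
                raise ValueError(
                    "tree has tips absent from the species list; "
                    "pass prune_extra=True to drop them")
            return self.prune_to(list(species)).covariance(species)

        et = self.edge_table()
        depths = et.depths()
        n = len(species)
        order = {sp: k for k, sp in enumerate(species)}
        C = np.zeros((n, n))
        # postorder accumulation of tip sets; cross-child tip pairs share
        # the current node as MRCA
        tipsets: dict[int, list[int]] = {}
        node_label = {j: l for l, j in et.tip_index.items()}
        for i in range(et.n_nodes - 1, -1, -1):
            if not et.children[i]:
                k = order[node_label[i]]
                tipsets[i] = [k]
                C[k, k] = depths[i]
                continue
            merged: list[int] = []
            for a_i, ci in enumerate(et.children[i]):
                for cj in et.children[i][a_i + 1:]:
                    for a in tipsets[ci]:
                        for b in tipsets[cj]:
                            C[a, b] = C[b, a] = depths[i]
            for ci in et.children[i]:
                merged.extend(tipsets.pop(ci))
            tipsets[i] = merged
        return C

    def mrca_index(self, a: str, b: str) -> int:
        """Node index (edge-table numbering) of the MRCA of two tips."""
        et = self.edge_table()
        anc_a = set()
        i = et.tip_index[a]
        while i != -1:
            anc_a.add(i)
            i = et.parent[i]
        j = et.tip_index[b]
        while j not in anc_a:
            j = et.parent[j]
        return j

    def path_to_ancestor(self, tip: str, ancestor_index: int) -> list[int]:
        """Node indices from *tip* up to *ancestor_index*, both inclusive."""
        et = self.edge_table()
        path = [et.tip_index[tip]]
        while path[-1] != ancestor_index:
            nxt = et.parent[path[-1]]
            if nxt == -1:
                raise ValueError("ancestor_index is not an ancestor of tip")
            path.append(nxt)
        return path

    def clade_edges(self, node_index: int) -> list[tuple[int, int, float]]:
        """(parent, child, length) for every edge inside the clade below a node."""
        et = self.edge_table()
        out: list[tuple[int, int, float]] = []
        stack = [node_index]
        while stack:
            i = stack.pop()
            for c in et.children[i]:
                out.append((i, c, et.length[c]))
                stack.append(c)
        return out


def phylo_covariance(tree: PhyloTree, species: list[str],
                     prune_extra: bool = False) -> np.ndarray:
    """Tip covariance matrix of *tree* in the order given by *species*."""
    return tree.covariance(species, prune_extra=prune_extra)
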