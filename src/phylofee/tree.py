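"""Rooted ultrametric phylogenies and the distance/covariance matrices built from them.

The phylogeny is the backbone of every comparative analysis in this package:
cophenetic (tip-to-tip) distances feed the phylogeny-vs-phenotype distance
correlation, and the Brownian-motion covariance matrix (shared root-to-MRCA
path lengths) underlies both Pagel's lambda estimation and trait imputation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "read_newick",
    "cophenetic_matrix",
    "bm_covariance",
    "pnnd",
]


class TreeError(ValueError):
    """Raised for malformed or unusable tree input."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, indexed by unique tip labels.

    Parameters
    ----------
    tree:
        The underlying :class:`dendropy.Tree` (rooted, every edge with a
        length except possibly the root edge, which is treated as 0).
    tolerance:
        Absolute tolerance for the ultrametricity check, as a fraction of
        tree height (default ``1e-6``).  Violations are reported via
        :attr:`is_ultrametric`, never silently repaired.
    """

    tree: dendropy.Tree
    tolerance: float = 1e-6
    tips: list[str] = field(init=False)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise TreeError("missing branch length on an internal or terminal edge")
            if node.edge.length < 0:
                raise TreeError(f"negative branch length {node.edge.length}")
        self.tips = sorted(labels)
        self._depths = self._compute_depths()

    def _compute_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth."""
        return max(self._depths.values())

    def depths(self) -> pd.Series:
        """Root-to-tip path length for every tip, in tip order."""
        return pd.Series([self._depths[t] for t in self.tips], index=self.tips, name="depth")

    @property
    def is_ultrametric(self) -> bool:
        d = self.depths().to_numpy()
        tol = self.tolerance * max(self.height, np.finfo(float).tiny)
        return float(d.max() - d.min()) <= tol

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1), tolerance=self.tolerance)


def _parse_newick(source: str, tolerance: float) -> Phylogeny:
    # dendropy silently tolerates missing branch lengths (edge.length None);
    # Phylogeny.__post_init__ turns those into errors.
    try:
        tree = dendropy.Tree.get(
            data=source,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise TreeError(f"malformed newick: {exc}") from exc
    phylo = Phylogeny(tree, tolerance=tolerance)
    if not phylo.is_ultrametric:
        d = phylo.depths().to_numpy()
        warnings.warn(
            "tree is not ultrametric within tolerance "
            f"(tip-depth spread {d.max() - d.min():.3g}, height {phylo.height:.3g}); "
            "proceeding, but Brownian-model analyses assume an ultrametric tree",
            stacklevel=3,
        )
    return phylo


def read_newick(path, tolerance: float = 1e-6) -> Phylogeny:
    """Read a rooted tree from a newick file.

    Branch lengths are mandatory on every non-root edge; duplicate or empty
    tip labels are errors.  An ultrametricity warning is emitted when tip
    depths differ by more than ``tolerance * height``.
    """
    if isinstance(path, io.StringIO):
        text = path.getvalue()
    else:
        with open(path) as fh:
            text = fh.read()
    return _parse_newick(text, tolerance)


def read_newick_string(newick: str, tolerance: float = 1e-6) -> Phylogeny:
    """Parse a newick string (convenience wrapper around :func:`read_newick`)."""
    return _parse_newick(newick, tolerance)


def cophenetic_matrix(phylo: Phylogeny) -> pd.DataFrame:
    """Tip-to-tip patristic distances: the sum of branch lengths on the path
    between each pair of tips.  Symmetric, zero diagonal, tips sorted."""
    pdm = phylo.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in phylo.tree.taxon_namespace if t.label in set(phylo.tips)}
    n = phylo.n_tips
    d = np.zeros((n, n))
    for i, a in enumerate(phylo.tips):
        for j in range(i + 1, n):
            dij = pdm.patristic_distance(taxa[a], taxa[phylo.tips[j]])
            d[i, j] = d[j, i] = dij
    return pd.DataFrame(d, index=phylo.tips, columns=phylo.tips)


def bm_covariance(phylo: Phylogeny) -> pd.DataFrame:
    """Brownian-motion covariance matrix of tip values.

    ``C[i, j]`` is the depth of the most recent common ancestor of tips *i*
    and *j* (the shared root-to-tip path length); the diagonal holds tip
    depths.  Computed from root paths, independently of the cophenetic
    matrix, so that the identity ``d_ij = C_ii + C_jj - 2 C_ij`` is a real
    cross-check rather than a tautology.
    """
    tips = phylo.tips
    # root path of cumulative depths per tip, as (node id -> depth) maps
    paths: list[dict[int, float]] = []
    for label in tips:
        leaf = next(
            l for l in phylo.tree.leaf_node_iter() if l.taxon.label == label
        )
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        # depth of each ancestor = tip depth minus length of edges below it
        depth = phylo._depths[label]
        anc = {}
        for node in chain:
            anc[id(node)] = depth
            depth -= node.edge.length or 0.0
        paths.append(anc)
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = phylo._depths[tips[i]]
        for j in range(i + 1, n):
            shared = set(paths[i]) & set(paths[j])
            # MRCA is the deepest node on both root paths
            C[i, j] = C[j, i] = max(paths[i][k] for k in shared)
    return pd.DataFrame(C, index=tips, columns=tips)


def pnnd(phylo: Phylogeny) -> pd.Series:
    """Phylogenetic nearest-neighbour distance: each tip's minimum cophenetic
    distance to any other tip.  Requires at least two tips."""
    if phylo.n_tips < 2:
        raise TreeError("PNND needs at least 2 tips")
    d = cophenetic_matrix(phylo).to_numpy().copy()
    np.fill_diagonal(d, np.inf)
    return pd.Series(d.min(axis=1), index=phylo.tips, name="pnnd")
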