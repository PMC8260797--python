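"""Phylogeny container, Newick I/O, and phylogenetic covariance matrices.

Under Brownian-motion trait evolution the expected covariance between two
tips equals the shared root-to-MRCA path length, and the variance of a tip
equals its root-to-tip depth.  Pagel's λ rescales the off-diagonal
(shared-history) part of that matrix while leaving tip variances untouched:

    C(λ)[i, j] = λ · C[i, j]   (i ≠ j),      C(λ)[i, i] = C[i, i].

λ is kept in [0, 1]: on non-ultrametric trees (branch lengths in
substitutions per site rather than time) λ > 1 can break positive
semi-definiteness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "parse_newick",
    "write_newick",
    "phylo_covariance",
    "lambda_transform",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian-motion covariance of tip values on a phylogeny.

    Attributes
    ----------
    labels : tuple of str
        Tip labels in Newick appearance order.  All trait vectors are
        aligned by label, never by position.
    matrix : ndarray of shape (n_tips, n_tips)
        Symmetric PSD matrix; ``matrix[i, j]`` is the root-to-MRCA path
        length for tips i and j, ``matrix[i, i]`` the root-to-tip depth.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if m.shape[0] != len(self.labels):
            raise ValueError("labels/matrix size mismatch")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.labels)

    def align(self, values, name: str = "trait") -> np.ndarray:
        """Return `values` (a mapping or pandas Series keyed by label, or a
        plain array already in label order) as an ndarray in label order."""
        if hasattr(values, "reindex"):  # pandas Series / DataFrame row
            missing = [l for l in self.labels if l not in values.index]
            if missing:
                raise KeyError(f"{name} missing species: {missing}")
            return np.asarray(values.reindex(list(self.labels)), dtype=float)
        if isinstance(values, dict):
            missing = [l for l in self.labels if l not in values]
            if missing:
                raise KeyError(f"{name} missing species: {missing}")
            return np.asarray([values[l] for l in self.labels], dtype=float)
        arr = np.asarray(values, dtype=float)
        if arr.shape[0] != self.n:
            raise ValueError(
                f"{name} has {arr.shape[0]} entries, expected {self.n}"
            )
        return arr


class Phylogeny:
    """A rooted phylogeny with branch lengths, backed by dendropy.

    Tip labels must be unique; branch lengths are non-negative real numbers
    in whatever unit the tree was inferred in (substitutions per site or
    arbitrary time).  Missing branch lengths are replaced by a configurable
    default (0 unless stated otherwise).
    """

    def __init__(self, tree: dendropy.Tree, default_edge_length: float = 0.0):
        self._tree = tree
        seen = set()
        for leaf in tree.leaf_node_iter():
            label = _leaf_label(leaf)
            if label is None:
                raise NewickError("tree contains an unlabeled tip")
            if label in seen:
                raise NewickError(f"duplicate tip label: {label!r}")
            seen.add(label)
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = default_edge_length
            elif edge.length < 0:
                raise NewickError(
                    f"negative branch length {edge.length} above "
                    f"{_describe_node(edge.head_node)}"
                )
        root_children = tree.seed_node.child_nodes()
        if len(root_children) > 2:
            warnings.warn(
                "tree has a basal polytomy (likely written unrooted); "
                "treating the polytomy as the root",
                stacklevel=3,
            )

    # -- constructors -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, default_edge_length: float = 0.0) -> "Phylogeny":
        return parse_newick(text, default_edge_length=default_edge_length)

    @classmethod
    def from_file(cls, path, default_edge_length: float = 0.0) -> "Phylogeny":
        with open(path) as fh:
            return parse_newick(fh.read(), default_edge_length=default_edge_length)

    # -- properties ---------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in Newick appearance (preorder) order."""
        return tuple(_leaf_label(l) for l in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    # -- I/O ----------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- comparative structure ----------------------------------------

    def covariance(self) -> PhyloCovariance:
        return phylo_covariance(self)

    def distance_matrix(self) -> PhyloCovariance:
        """Patristic (tip-to-tip path length) distances, same label order
        as :meth:`covariance`.  Returned in a PhyloCovariance shell for the
        label bookkeeping; the matrix is a distance, not a covariance."""
        cov = self.covariance()
        depths = np.diag(cov.matrix)
        d = depths[:, None] + depths[None, :] - 2.0 * cov.matrix
        np.fill_diagonal(d, 0.0)
        return PhyloCovariance(cov.labels, d)

    def __repr__(self):
        return f"Phylogeny(n_tips={self.n_tips})"


def _leaf_label(leaf) -> str | None:
    if leaf.taxon is not None and leaf.taxon.label is not None:
        return leaf.taxon.label.replace(" ", "_")
    return leaf.label


def _describe_node(node) -> str:
    if node.is_leaf():
        return f"tip {_leaf_label(node)!r}"
    return "an internal node"


def parse_newick(text: str, default_edge_length: float = 0.0) -> Phylogeny:
    """Parse a single Newick tree.

    Raises
    ------
    NewickError
        On malformed input (with dendropy's positional message) or
        duplicate tip labels.
    """
    if not text or not text.strip():
        raise NewickError("empty Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree, default_edge_length=default_edge_length)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance matrix of a phylogeny.

    ``C[i, j]`` is the path length from the root to the most recent common
    ancestor of tips i and j; the diagonal holds root-to-tip depths.
    Computed by a single preorder pass accumulating node depths and filling
    cross-subtree blocks at each internal node.
    """
    labels = tree.tip_labels
    n = len(labels)
    if n < 2:
        raise ValueError("covariance requires a tree with >= 2 tips")
    index = {lab: i for i, lab in enumerate(labels)}
    C = np.zeros((n, n))

    # node depth from root, and tip index sets per subtree
    dtree = tree._tree
    depth: dict[int, float] = {id(dtree.seed_node): 0.0}
    tipsets: dict[int, list[int]] = {}
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = index[_leaf_label(node)]
            tipsets[id(node)] = [i]
            C[i, i] = depth[id(node)]
        else:
            children = node.child_nodes()
            sets = [tipsets.pop(id(c)) for c in children]
            d = depth[id(node)]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        C[i, sets[b]] = d
                        C[sets[b], i] = d
            merged: list[int] = []
            for s in sets:
                merged.extend(s)
            tipsets[id(node)] = merged
    return PhyloCovariance(labels, C)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Apply Pagel's λ transform: multiply off-diagonals by ``lam``.

    ``lam`` must lie in [0, 1]; λ=1 returns an equal matrix, λ=0 a diagonal
    one.  The result is PSD whenever the input is (it is a convex
    combination of the input and its diagonal).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return PhyloCovariance(cov.labels, lambda_transform_matrix(cov.matrix, lam))


def lambda_transform_matrix(C: np.ndarray, lam: float) -> np.ndarray:
    """λ transform on a raw matrix (no label bookkeeping). 0 ≤ lam ≤ 1."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out
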