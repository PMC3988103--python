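"""Trees and phylogenetic covariance.

Newick I/O is backed by dendropy. The phylogenetic variance-covariance (VCV)
matrix of a rooted tree has entry (i, j) equal to the total branch length
shared by the root-to-tip paths of tips i and j, i.e. the depth of their most
recent common ancestor; diagonals are root-to-tip distances. Under Brownian
motion, trait covariances among species are proportional to this matrix.

Pagel's lambda rescales the off-diagonal (shared-history) part: V(lam) =
lam * V + (1 - lam) * diag(V). lam = 1 is full Brownian covariance, lam = 0
phylogenetic independence.

The default study tree is an equal-branch-length cladogram of the eight
bothriurid species, congeners grouped in clades (a punctuated-evolution
convention: change proportional to cladogenesis events, not time).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import dendropy
import numpy as np

from .errors import PhyloError

DEFAULT_BRANCH_LENGTH = 1.0


def _norm(label: str) -> str:
    return " ".join(str(label).replace("_", " ").split())


class Phylogeny:
    """Rooted tree with unique tip labels and non-negative branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = self.tip_labels
        if len(labels) < 2:
            raise PhyloError("a phylogeny needs at least 2 tips")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise PhyloError(f"duplicate tip label(s): {dup}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise PhyloError("negative branch length")

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [_norm(leaf.taxon.label) for leaf in self._tree.leaf_node_iter()]

    def depths(self) -> dict[str, float]:
        """Root-to-tip distance per tip label."""
        out = {}
        for leaf in self._tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[_norm(leaf.taxon.label)] = d
        return out

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string; missing branch lengths default to 1.

    The "assumed equal" convention: a topology-only Newick such as
    ``"((A,B),C);"`` becomes a tree with every branch of length 1. The root
    has no subtending branch.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhyloError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        elif node.edge.length is None:
            node.edge.length = DEFAULT_BRANCH_LENGTH
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def default_cladogram() -> Phylogeny:
    """The study cladogram for the eight bothriurid species.

    Genus clades (Bothriurus, Brachistosternus, Timogenes, Urophonius) with
    every branch length 1; the above-genus arrangement
    ((Bothriurus, Brachistosternus), (Timogenes, Urophonius)) is a documented
    working assumption — supply your own Newick to override it.
    """
    ref = resources.files("scorpallo.data") / "bothriuridae_default.nwk"
    return parse_newick(ref.read_text())


def balanced_tree(n_tips: int, branch_length: float = 1.0) -> Phylogeny:
    """Fully balanced binary tree with ``n_tips`` (a power of two) leaves.

    Tips are labelled ``t1..tn``. Used for simulation studies where a regular
    topology with substantial shared history is wanted.
    """
    if n_tips < 2 or n_tips & (n_tips - 1):
        raise PhyloError("n_tips must be a power of two >= 2")

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"t{lo + 1}:{branch_length}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{branch_length}"

    mid = n_tips // 2
    return parse_newick(f"({build(0, mid)},{build(mid, n_tips)});")


@dataclass(frozen=True)
class PhyloCovariance:
    """n x n shared-path-length matrix with its tip order and lambda."""

    matrix: np.ndarray
    tip_order: tuple[str, ...]
    lam: float = 1.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.tip_order):
            raise PhyloError("covariance matrix shape does not match tip order")
        if not np.allclose(m, m.T):
            raise PhyloError("covariance matrix must be symmetric")
        object.__setattr__(self, "matrix", m)


def vcv_from_tree(phy: Phylogeny, tip_order=None) -> PhyloCovariance:
    """Phylogenetic VCV: entry (i, j) = depth of the MRCA of tips i and j.

    ``tip_order`` (default: the tree's own tip order) must be a permutation
    of the tip labels; rows/columns follow it, so a trait table aligned to
    the same species order can be used directly.
    """
    labels = phy.tip_labels
    if tip_order is None:
        order = labels
    else:
        order = [_norm(s) for s in tip_order]
        if sorted(order) != sorted(labels):
            unknown = sorted(set(order) - set(labels))
            missing = sorted(set(labels) - set(order))
            raise PhyloError(
                f"tip_order mismatch (unknown: {unknown}, missing from order: {missing})"
            )
    idx = {name: i for i, name in enumerate(order)}
    n = len(order)
    V = np.zeros((n, n))

    # Depth-first pass: each internal node sets the covariance of tip pairs
    # whose MRCA it is (pairs drawn from distinct child subtrees).
    depth: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    for node in phy.tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[id(parent)] + (node.edge.length or 0.0)
        depth[id(node)] = d
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[_norm(node.taxon.label)]
            below[id(node)] = [i]
            V[i, i] = depth[id(node)]
            continue
        child_sets = [below[id(c)] for c in node.child_nodes()]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        V[i, j] = V[j, i] = depth[id(node)]
        below[id(node)] = [i for s in child_sets for i in s]
    return PhyloCovariance(matrix=V, tip_order=tuple(order), lam=1.0)


def lambda_transform(V: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda rescaling: off-diagonals times lam, diagonal kept.

    Equivalently V(lam) = lam * V + (1 - lam) * diag(V), so the result is
    positive semidefinite for every lam in [0, 1].
    """
    if not 0.0 <= lam <= 1.0:
        raise PhyloError(f"lambda must lie in [0, 1], got {lam}")
    m = V.matrix * lam
    np.fill_diagonal(m, np.diag(V.matrix))
    return replace(V, matrix=m, lam=lam)
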