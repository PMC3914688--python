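"""Light phylogenetic tree structure shared by the likelihood engine,
parsimony mapping and clade queries.

Trees are stored rooted (the likelihood root is arbitrary for reversible
models); an unrooted binary tree is represented by a trifurcating root.
Newick parsing goes through scikit-bio; writing is plain formatting.
Neighbor joining on uncorrected distances provides starting trees.
"""

from __future__ import annotations

import io

import numpy as np

import skbio
from skbio import DistanceMatrix


class Node:
    __slots__ = ("name", "length", "children", "parent", "support")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.support: float | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.name or '(internal)'}>"


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # -- traversal -----------------------------------------------------------

    def postorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def preorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_tip]

    # -- copying -------------------------------------------------------------

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            c = Node(node.name, node.length)
            c.support = node.support
            for child in node.children:
                c.add(clone(child))
            return c

        return Tree(clone(self.root))

    # -- newick --------------------------------------------------------------

    def to_newick(self, include_support: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                if include_support and node.support is not None:
                    label = f"({inner}){node.support:g}"
                else:
                    label = f"({inner}){node.name or ''}"
            if node.length is not None:
                label += f":{node.length:.10g}"
            return label

        return fmt(self.root) + ";"

    # -- surgery -------------------------------------------------------------

    def unroot(self) -> "Tree":
        """Collapse a degree-2 root so the root has >= 3 children (if possible)."""
        root = self.root
        while len(root.children) == 2:
            left, right = root.children
            keep, fold = (left, right) if not left.is_tip else (right, left)
            if keep.is_tip:  # two-taxon tree, nothing to collapse
                break
            # absorb `keep`: its children become root children; `fold` keeps
            # the combined branch length
            if fold.length is not None or keep.length is not None:
                fold.length = (fold.length or 0.0) + (keep.length or 0.0)
            root.children = [fold] + keep.children
            for c in keep.children:
                c.parent = root
            fold.parent = root
        return self

    def suppress_unifurcations(self) -> "Tree":
        for node in self.postorder():
            node.children = [c for c in node.children]
        changed = True
        while changed:
            changed = False
            for node in self.postorder():
                if node is self.root:
                    continue
                if len(node.children) == 1:
                    (child,) = node.children
                    if child.length is not None or node.length is not None:
                        child.length = (child.length or 0.0) + (node.length or 0.0)
                    parent = node.parent
                    parent.children[parent.children.index(node)] = child
                    child.parent = parent
                    changed = True
        if len(self.root.children) == 1 and not self.root.children[0].is_tip:
            self.root = self.root.children[0]
            self.root.parent = None
            self.root.length = None
        return self

    def prune_tips(self, names: set[str]) -> "Tree":
        """Remove the named tips (and resulting unifurcations)."""
        for tip in [t for t in self.tips() if t.name in names]:
            parent = tip.parent
            if parent is None:
                raise ValueError("cannot prune the only node")
            parent.children.remove(tip)
        self.suppress_unifurcations()
        self.unroot()
        return self

    # -- bipartitions and clades ---------------------------------------------

    def bipartitions(self) -> dict[frozenset, Node]:
        """Canonical non-trivial bipartitions of the unrooted tree.

        Each internal edge is keyed by the tip-set on the side *not*
        containing the lexicographically smallest tip name.
        """
        all_tips = frozenset(self.tip_names())
        ref = min(all_tips)
        out: dict[frozenset, Node] = {}
        subtree: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_tip:
                subtree[id(node)] = frozenset([node.name])
            else:
                subtree[id(node)] = frozenset().union(
                    *(subtree[id(c)] for c in node.children)
                )
            if node is self.root or node.parent is None:
                continue
            side = subtree[id(node)]
            if len(side) < 2 or len(all_tips - side) < 2:
                continue
            canon = side if ref not in side else all_tips - side
            out[canon] = node
        return out

    def is_monophyletic(self, taxa: set[str]) -> bool:
        all_tips = frozenset(self.tip_names())
        taxa = frozenset(taxa)
        unknown = taxa - all_tips
        if unknown:
            raise KeyError(f"taxa not in tree: {sorted(unknown)}")
        if not taxa or taxa == all_tips:
            raise ValueError("taxon set must be a non-empty proper subset")
        if len(taxa) == 1 or len(all_tips - taxa) == 1:
            return True
        ref = min(all_tips)
        canon = taxa if ref not in taxa else all_tips - taxa
        return canon in self.bipartitions()


def parse_newick(newick: str) -> Tree:
    """Parse a Newick string (internal numeric labels become supports)."""
    sk = skbio.TreeNode.read(io.StringIO(newick), format="newick")

    def convert(sknode) -> Node:
        node = Node(sknode.name, sknode.length)
        for child in sknode.children:
            node.add(convert(child))
        if node.children and node.name is not None:
            try:
                node.support = float(node.name)
                node.name = None
            except ValueError:
                pass
        return node

    return Tree(convert(sk))


def nj_tree(distances: np.ndarray, taxa: list[str]) -> Tree:
    """Neighbor-joining tree (scikit-bio), unrooted, negative lengths clipped."""
    dm = DistanceMatrix(np.asarray(distances, dtype=float), ids=list(taxa))
    sk = skbio.tree.nj(dm)
    tree = parse_newick(str(sk))
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    tree.suppress_unifurcations()
    tree.unroot()
    return tree


def logdet_distances(chars: np.ndarray, n_states: int) -> np.ndarray:
    """LogDet/paralinear distances, robust to compositional heterogeneity.

    d = -(1/k) [ln det F - (ln det D_x + ln det D_y)/2] with F the joint
    state frequency matrix of a taxon pair and D the marginal diagonals.
    A pseudocount keeps det F positive for sparse/saturated pairs; pairs
    with no shared sites fall back to a fixed large distance.
    """
    n = chars.shape[0]
    k = n_states
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = chars[i], chars[j]
            ok = (a < k) & (b < k)
            if not ok.any():
                dist[i, j] = dist[j, i] = 3.0
                continue
            F = np.zeros((k, k))
            np.add.at(F, (a[ok], b[ok]), 1.0)
            F += 0.1
            F /= F.sum()
            sign, logdet = np.linalg.slogdet(F)
            if sign <= 0:
                d = 3.0
            else:
                dx = np.log(F.sum(axis=1)).sum()
                dy = np.log(F.sum(axis=0)).sum()
                d = max(-(logdet - (dx + dy) / 2) / k, 0.0)
            dist[i, j] = dist[j, i] = d
    return dist


def p_distances(chars: np.ndarray, n_states: int) -> np.ndarray:
    """Uncorrected pairwise mismatch fractions over shared non-missing sites.

    ``chars`` is an integer matrix (ntaxa, nsites); codes >= ``n_states``
    are missing.  Taxon pairs with no shared sites get distance 0.75.
    """
    n = chars.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = chars[i], chars[j]
            ok = (a < n_states) & (b < n_states)
            d = float((a[ok] != b[ok]).mean()) if ok.any() else 0.75
            dist[i, j] = dist[j, i] = d
    return dist
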