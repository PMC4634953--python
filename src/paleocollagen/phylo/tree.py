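"""Phylogenetic tree container and topology utilities.

A light rooted-representation tree: unrooted topologies are stored with a
trifurcating root, all other internal nodes binary. Newick parsing/writing
delegates to dendropy; neighbour-joining start trees come from scikit-bio.
"""

from __future__ import annotations

import itertools

import numpy as np


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("label", "length", "children", "parent", "support")

    def __init__(self, label=None, length=0.0):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.support: float | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()


class Tree:
    """A tree rooted for computation; trifurcating root <=> unrooted topology."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True)
        return cls._from_dendropy(dtree)

    @classmethod
    def _from_dendropy(cls, dtree) -> "Tree":
        def convert(dnode):
            label = dnode.taxon.label if dnode.taxon is not None else None
            node = Node(label=label, length=dnode.edge.length or 0.0)
            if label is None and dnode.label is not None:
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    node.label = dnode.label
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self, include_support: bool = False, precision: int = 8) -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                body = "(" + ",".join(render(c) for c in node.children) + ")"
                if include_support and node.support is not None:
                    body += f"{node.support:g}"
                elif node.label:
                    body += node.label
            if node.parent is not None:
                body += f":{node.length:.{precision}g}"
            return body

        return render(self.root) + ";"

    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            new = Node(label=node.label, length=node.length)
            new.support = node.support
            for c in node.children:
                new.add_child(dup(c))
            return new

        return Tree(dup(self.root))

    # -- inspection --------------------------------------------------------

    def leaves(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def postorder(self):
        return self.root.postorder()

    def preorder(self):
        return self.root.preorder()

    def find_leaf(self, label: str) -> Node:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise TreeError(f"leaf {label!r} not found in tree")

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.postorder() if not n.is_leaf]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits as frozensets of leaf labels (smaller or
        lexicographically-first side), invariant to rooting."""
        all_labels = frozenset(self.leaf_labels())
        splits = set()
        for node in self.root.postorder():
            if node.is_leaf or node.parent is None:
                continue
            side = frozenset(l.label for l in node.postorder() if l.is_leaf)
            other = all_labels - side
            if len(side) < 2 or len(other) < 2:
                continue
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits

    # -- manipulation ------------------------------------------------------

    def unroot(self) -> "Tree":
        """Collapse a bifurcating root into a trifurcation (in place).

        The edge length of the dissolved internal child is folded onto its
        sibling so path lengths are preserved.
        """
        root = self.root
        if len(root.children) == 2:
            a, b = root.children
            promoted = b if not b.is_leaf else a
            if promoted.is_leaf:  # two-leaf tree: nothing to collapse
                return self
            other = a if promoted is b else b
            other.length += promoted.length
            root.children = [other] + promoted.children
            for c in root.children:
                c.parent = root
            promoted.children = []
        return self

    def reroot_at_edge_midpoint(self, node: Node) -> "Tree":
        """Return a copy rooted at the midpoint of the edge above ``node``."""
        path_labels = _path_identity(node)
        new = self.copy()
        target = _follow_path(new.root, path_labels)
        return Tree(_reroot_edge(new.root, target))

    def root_at_outgroup(self, outgroup_label: str) -> "Tree":
        """Root on the outgroup's pendant edge (split at its midpoint)."""
        leaf = self.find_leaf(outgroup_label)
        return self.reroot_at_edge_midpoint(leaf)


def _path_identity(node: Node) -> list[int]:
    path = []
    while node.parent is not None:
        path.append(node.parent.children.index(node))
        node = node.parent
    return list(reversed(path))


def _follow_path(root: Node, path: list[int]) -> Node:
    node = root
    for idx in path:
        node = node.children[idx]
    return node


def _reroot_edge(old_root: Node, node: Node) -> Node:
    """Re-hang the tree from the midpoint of the edge above ``node``."""
    if node.parent is None:
        raise TreeError("cannot root at the root's own (non-existent) edge")
    half = node.length / 2.0
    new_root = Node()
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    node.length = half
    # reverse all edges on the path from `parent` up to the old root
    _flip_upward(parent)
    parent.length = half
    new_root.add_child(node)
    new_root.add_child(parent)
    # an old root left with a single child is redundant: splice it out
    _suppress_unifurcations(new_root)
    return new_root


def _flip_upward(node: Node) -> None:
    """Reverse parent pointers so ``node`` becomes the top of its old path."""
    parent = node.parent
    if parent is None:
        return
    _flip_upward(parent)
    parent.children.remove(node)
    node.parent = None
    length = node.length
    node.children.append(parent)
    parent.parent = node
    parent.length = length


def _suppress_unifurcations(root: Node) -> None:
    for node in list(root.postorder()):
        if node is root:
            continue
        if len(node.children) == 1:
            (child,) = node.children
            child.length += node.length
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
    # root itself
    while len(root.children) == 1:
        (child,) = root.children
        for gc in child.children:
            gc.length += 0.0
        root.children = child.children
        for gc in root.children:
            gc.parent = root


def rf_distance(a: Tree, b: Tree) -> int:
    """Robinson-Foulds distance: symmetric difference of non-trivial splits."""
    la, lb = set(a.leaf_labels()), set(b.leaf_labels())
    if la != lb:
        raise TreeError("trees must share an identical leaf set")
    return len(a.bipartitions() ^ b.bipartitions())


# -- distances and neighbour joining --------------------------------------


def p_distance_matrix(sequences: dict[str, str],
                      missing: str = "X?-*") -> tuple[np.ndarray, list[str]]:
    """Pairwise proportion-of-differences with pairwise deletion of missing sites."""
    taxa = list(sequences)
    n = len(taxa)
    arrs = {t: np.frombuffer(sequences[t].encode(), dtype="S1") for t in taxa}
    miss = {m.encode() for m in missing}
    ok = {t: ~np.isin(arrs[t], list(miss)) for t in taxa}
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = ok[taxa[i]] & ok[taxa[j]]
        m = int(both.sum())
        if m == 0:
            d[i, j] = d[j, i] = 0.75  # no overlap: maximally uninformative
            continue
        diff = int((arrs[taxa[i]][both] != arrs[taxa[j]][both]).sum())
        d[i, j] = d[j, i] = diff / m
    return d, taxa


def nj_tree(distances: np.ndarray, taxa: list[str]) -> Tree:
    """Neighbour-joining tree (scikit-bio), returned unrooted with
    non-negative branch lengths."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(distances, ids=taxa)
    tree = Tree.from_newick(str(nj(dm)))
    for node in tree.postorder():
        if node.length < 0:
            node.length = 1e-8
    tree.unroot()
    return tree
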