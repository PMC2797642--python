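"""Unrooted phylogenetic trees with branch lengths and support labels.

Trees are stored rooted at an internal trifurcation purely as a data
structure; all semantics (bipartitions, monophyly, Robinson-Foulds) are
unrooted. Newick parsing is delegated to dendropy; writing is done here so
output is deterministic.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy


def _merge_support(a: Optional[float], b: Optional[float]) -> Optional[float]:
    """Support of an edge formed by merging two edges whose bipartitions
    coincide after pruning: keep the stronger evidence."""
    if a is None:
        return b
    if b is None:
        return a
    return max(a, b)


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: float = 0.0,
        support: Optional[float] = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name or ''} {kind} len={self.length:.4g}>"


class PhyloTree:
    """Unrooted tree; ``root`` is an arbitrary internal node (degree 3 in a
    fully unrooted binary tree)."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal --------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def leaves(self) -> list[Node]:
        return [nd for nd in self.postorder() if nd.is_leaf]

    def leaf_names(self) -> list[str]:
        return [nd.name for nd in self.leaves()]

    def leaf_set(self) -> frozenset:
        return frozenset(self.leaf_names())

    def find_leaf(self, name: str) -> Node:
        for nd in self.leaves():
            if nd.name == name:
                return nd
        raise KeyError(f"leaf {name!r} not in tree")

    def copy(self) -> "PhyloTree":
        def clone(nd: Node) -> Node:
            c = Node(nd.name, nd.length, nd.support)
            for ch in nd.children:
                c.add_child(clone(ch))
            return c

        return PhyloTree(clone(self.root))

    def n_edges(self) -> int:
        return sum(1 for nd in self.postorder() if nd.parent is not None)

    # -- unrooted semantics ------------------------------------------------

    def clade_sets(self) -> dict:
        """Map each non-root node to the frozenset of leaf names below it."""
        sets: dict[Node, frozenset] = {}
        for nd in self.postorder():
            if nd.is_leaf:
                sets[nd] = frozenset([nd.name])
            else:
                sets[nd] = frozenset().union(*(sets[c] for c in nd.children))
        return sets

    def bipartitions(self) -> set:
        """Non-trivial bipartitions, each canonicalized as the side NOT
        containing the lexicographically smallest leaf."""
        all_leaves = self.leaf_set()
        ref = min(all_leaves)
        out = set()
        sets = self.clade_sets()
        for nd, below in sets.items():
            if nd.parent is None or len(below) < 2 or len(below) > len(all_leaves) - 2:
                continue
            side = all_leaves - below if ref in below else below
            out.add(side)
        return out

    def is_monophyletic(self, taxa) -> bool:
        """True iff some edge bipartitions ``taxa`` against the rest
        (unrooted convention; trivial sets are monophyletic)."""
        taxa = frozenset(taxa)
        all_leaves = self.leaf_set()
        unknown = taxa - all_leaves
        if unknown:
            raise KeyError(f"taxa not in tree: {sorted(unknown)}")
        if len(taxa) <= 1 or taxa == all_leaves:
            return True
        complement = all_leaves - taxa
        for nd, below in self.clade_sets().items():
            if nd.parent is None:
                continue
            if below == taxa or below == complement:
                return True
        return False

    def mrca_edge_node(self, taxa) -> Node:
        """Node whose below-edge bipartition separates ``taxa`` (which must
        be monophyletic in the unrooted sense); re-rooting is applied if the
        clade only exists on the complement side."""
        taxa = frozenset(taxa)
        sets = self.clade_sets()
        for nd, below in sets.items():
            if nd.parent is not None and below == taxa:
                return nd
        # clade may only appear as a complement; reroot at a leaf outside it
        outside = sorted(self.leaf_set() - taxa)
        if not outside:
            raise ValueError("cannot take the full leaf set as a clade")
        self.reroot_near(outside[0])
        for nd, below in self.clade_sets().items():
            if nd.parent is not None and below == taxa:
                return nd
        raise ValueError("taxa are not monophyletic")

    def reroot_near(self, leaf_name: str) -> None:
        """Re-root (as data structure) at the internal node adjacent to the
        given leaf. Unrooted semantics are unchanged."""
        leaf = self.find_leaf(leaf_name)
        new_root = leaf.parent
        if new_root is None or new_root is self.root:
            return
        # reverse parent pointers along the path to the old root; the edge
        # between path[i] and path[i+1] keeps path[i]'s original length/support
        path = []
        nd = new_root
        while nd is not None:
            path.append(nd)
            nd = nd.parent
        orig_len = [nd.length for nd in path]
        orig_sup = [nd.support for nd in path]
        for i in range(len(path) - 1):
            child, par = path[i], path[i + 1]
            par.children.remove(child)
            child.add_child(par)
            par.length = orig_len[i]
            par.support = orig_sup[i]
        new_root.parent = None
        new_root.length = 0.0
        new_root.support = None
        self.root = new_root
        self.suppress_unifurcations()

    def suppress_unifurcations(self) -> None:
        """Merge out degree-2 nodes, summing the two incident edge lengths."""
        changed = True
        while changed:
            changed = False
            for nd in list(self.postorder()):
                if nd.is_leaf:
                    continue
                if nd.parent is None and len(nd.children) == 1:
                    child = nd.children[0]
                    if child.is_leaf:
                        continue
                    child.parent = None
                    child.length = 0.0
                    self.root = child
                    changed = True
                    break
                if nd.parent is not None and len(nd.children) == 1:
                    child = nd.children[0]
                    child.length += nd.length
                    child.support = _merge_support(child.support, nd.support)
                    par = nd.parent
                    par.children[par.children.index(nd)] = child
                    child.parent = par
                    changed = True
        if len(self.root.children) == 2 and not all(
            c.is_leaf for c in self.root.children
        ):
            a, b = self.root.children
            internal = a if not a.is_leaf else b
            other = b if internal is a else a
            internal.parent = None
            other.length += internal.length
            other.support = _merge_support(other.support, internal.support)
            internal.length = 0.0
            internal.support = None
            internal.add_child(other)
            self.root = internal

    # -- distances --------------------------------------------------------

    def rf_distance(self, other: "PhyloTree") -> int:
        """Robinson-Foulds distance: symmetric difference of the two trees'
        non-trivial bipartition sets."""
        if self.leaf_set() != other.leaf_set():
            raise ValueError("trees have different leaf sets")
        return len(self.bipartitions() ^ other.bipartitions())

    def same_topology(self, other: "PhyloTree") -> bool:
        return self.leaf_set() == other.leaf_set() and self.rf_distance(other) == 0

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )

        def convert(dnode) -> Node:
            support = None
            name = None
            if dnode.is_leaf():
                name = dnode.taxon.label if dnode.taxon else dnode.label
            elif dnode.label is not None:
                try:
                    support = float(dnode.label)
                except ValueError:
                    name = dnode.label
            nd = Node(name=name, support=support)
            nd.length = dnode.edge.length if dnode.edge.length is not None else 0.0
            for ch in dnode.child_nodes():
                nd.add_child(convert(ch))
            return nd

        tree = cls(convert(dt.seed_node))
        tree.root.length = 0.0
        tree.suppress_unifurcations()
        return tree

    @classmethod
    def read_newick(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def read_newick_list(cls, path) -> list["PhyloTree"]:
        trees = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    trees.append(cls.from_newick(line))
        return trees

    def to_newick(self, lengths: bool = True, support: bool = True) -> str:
        def fmt(nd: Node) -> str:
            if nd.is_leaf:
                body = nd.name or ""
            else:
                body = "(" + ",".join(fmt(c) for c in nd.children) + ")"
                if support and nd.support is not None and nd.parent is not None:
                    body += format(nd.support, "g")
                elif nd.name:
                    body += nd.name
            if lengths and nd.parent is not None:
                body += f":{nd.length:.10g}"
            return body

        return fmt(self.root) + ";"

    def write_newick(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")
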