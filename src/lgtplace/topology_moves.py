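"""Focal-clade extraction and constrained enumeration of alternative
placements (regrafts) on an unrooted tree.

A placement set is built by pruning the focal clade, filtering the pruned
tree's edges through scope / protected-clade / support constraints, and
regrafting the clade at the midpoint of every legal edge. The placement
that recreates the base topology is excluded and duplicates are removed by
bipartition-set equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phylo_core.tree import Node, PhyloTree


class InvalidCladeError(ValueError):
    pass


class DegenerateMoveError(ValueError):
    pass


@dataclass(frozen=True)
class PlacementConstraints:
    """Constraints on where a focal clade may be re-attached.

    ``protected_clades`` must stay monophyletic and may not be entered
    (their stem edge remains a legal attachment point). Edges with support
    at or above ``support_threshold`` are never broken. ``scope``, if
    given, restricts attachments to edges inside that leaf set.
    """

    protected_clades: tuple = ()
    support_threshold: float = 70.0
    scope: frozenset | None = None

    def __post_init__(self):
        object.__setattr__(
            self,
            "protected_clades",
            tuple(frozenset(c) for c in self.protected_clades),
        )
        if self.scope is not None:
            object.__setattr__(self, "scope", frozenset(self.scope))


@dataclass(frozen=True)
class MoveDescriptor:
    """Names the attachment edge by its post-order index in the pruned tree
    and the leaf set below it."""

    edge_index: int
    edge_clade: tuple

    def __str__(self) -> str:
        preview = ",".join(self.edge_clade[:3])
        if len(self.edge_clade) > 3:
            preview += ",..."
        return f"edge{self.edge_index}[{preview}]"


@dataclass
class TopologySet:
    base_tree: PhyloTree
    focal_taxa: frozenset
    alternatives: list = field(default_factory=list)  # (PhyloTree, MoveDescriptor)

    @property
    def trees(self) -> list[PhyloTree]:
        return [self.base_tree] + [t for t, _ in self.alternatives]

    def __len__(self) -> int:
        return 1 + len(self.alternatives)


def check_monophyly(tree: PhyloTree, taxa) -> bool:
    """True iff some edge of the unrooted tree bipartitions ``taxa``
    against all remaining leaves."""
    return tree.is_monophyletic(taxa)


def rf_distance(tree1: PhyloTree, tree2: PhyloTree) -> int:
    return tree1.rf_distance(tree2)


def _copy_with_map(tree: PhyloTree):
    mapping = {}

    def clone(nd: Node) -> Node:
        c = Node(nd.name, nd.length, nd.support)
        mapping[id(nd)] = c
        for ch in nd.children:
            c.add_child(clone(ch))
        return c

    return PhyloTree(clone(tree.root)), mapping


def extract_clade(tree: PhyloTree, focal) -> tuple[PhyloTree, PhyloTree, Node]:
    """Detach a monophyletic focal clade.

    Returns ``(focal_subtree, pruned_tree, stem_node)`` where ``stem_node``
    is the pruned-tree node under the edge formed by merging the two edges
    that flanked the original attachment (regrafting there recreates the
    base topology). The input tree is not modified.

    Raises
    ------
    InvalidCladeError
        If ``focal`` is not monophyletic (no silent MRCA superset is taken).
    """
    focal = frozenset(focal)
    if not tree.is_monophyletic(focal):
        raise InvalidCladeError(f"focal taxa are not monophyletic: {sorted(focal)}")
    if len(tree.leaf_set() - focal) < 2:
        raise InvalidCladeError("pruned tree needs at least 2 remaining leaves")
    work = tree.copy()
    clade = work.mrca_edge_node(focal)
    parent = clade.parent
    parent.children.remove(clade)
    clade.parent = None
    clade.length = 0.0
    focal_subtree = PhyloTree(clade)
    # candidates for the merged edge: the former siblings of the clade
    candidates = list(parent.children)
    work.suppress_unifurcations()
    pruned_nodes = set(id(nd) for nd in work.postorder())
    stem = None
    for cand in candidates:
        if id(cand) in pruned_nodes and cand.parent is not None:
            stem = cand
            break
    if stem is None:  # pragma: no cover - defensive
        raise RuntimeError("failed to locate merged stem edge")
    return focal_subtree, work, stem


def regraft(
    pruned: PhyloTree,
    focal_subtree: PhyloTree,
    edge_node: Node,
    stem_length: float | None = None,
) -> PhyloTree:
    """Attach ``focal_subtree`` at the midpoint of the edge above
    ``edge_node``; the focal stem defaults to half the broken edge length.
    Returns a new tree; inputs are untouched."""
    tree, mapping = _copy_with_map(pruned)
    target = mapping[id(edge_node)]
    if target.parent is None:
        raise ValueError("cannot attach on the root node (no edge above)")
    parent = target.parent
    half = target.length / 2.0
    joint = Node(length=half)
    parent.children[parent.children.index(target)] = joint
    joint.parent = parent
    target.length = half
    joint.add_child(target)
    graft = focal_subtree.copy().root
    graft.length = stem_length if stem_length is not None else max(half, 1e-8)
    joint.add_child(graft)
    return tree


def enumerate_placements(
    tree: PhyloTree,
    focal,
    constraints: PlacementConstraints | None = None,
) -> TopologySet:
    """Enumerate all legal alternative placements of ``focal``.

    Candidate edges of the pruned tree must lie within ``scope`` (when
    given), must not be strictly internal to a protected clade, and must
    have support below the threshold (or none). One alternative per edge,
    ordered by post-order edge index; the base topology is excluded and
    duplicates are dropped by bipartition-set equality.
    """
    constraints = constraints or PlacementConstraints()
    focal = frozenset(focal)
    focal_subtree, pruned, _ = extract_clade(tree, focal)

    below = pruned.clade_sets()
    pruned_leaves = pruned.leaf_set()
    for prot in constraints.protected_clades:
        scoped = frozenset(prot) & pruned_leaves
        if len(scoped) > 1 and not pruned.is_monophyletic(scoped):
            raise InvalidCladeError(
                f"protected clade is not a clade of the pruned tree: {sorted(prot)}"
            )

    base_bip = tree.bipartitions()
    seen = {frozenset(base_bip)}
    alternatives = []
    for idx, nd in enumerate(pruned.postorder()):
        if nd.parent is None:
            continue
        clade = below[nd]
        if constraints.scope is not None and not clade <= constraints.scope:
            continue
        if any(clade < prot for prot in constraints.protected_clades):
            continue
        if nd.support is not None and nd.support >= constraints.support_threshold:
            continue
        alt = regraft(pruned, focal_subtree, nd)
        key = frozenset(alt.bipartitions())
        if key in seen:
            continue
        seen.add(key)
        alternatives.append((alt, MoveDescriptor(idx, tuple(sorted(clade)))))
    return TopologySet(tree.copy(), focal, alternatives)
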