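"""Tree sampling, LGT grafting, and sequence simulation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..phylo_core.alignment import MISSING, AminoAlignment
from ..phylo_core.models import SubstModel, parse_model_spec
from ..phylo_core.tree import Node, PhyloTree
from ..topology_moves import (
    DegenerateMoveError,
    InvalidCladeError,
    extract_clade,
    regraft,
)


def _random_join_topology(labels: list[str], rng: np.random.Generator) -> Node:
    """Uniform coalescent-style topology: repeatedly join two random
    lineages; the last three meet at the (trifurcating) root."""
    lineages = [Node(name=l) for l in labels]
    while len(lineages) > 3:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        joint = Node()
        joint.add_child(lineages[i])
        joint.add_child(lineages[j])
        lineages[j:j + 1] = []
        lineages[i] = joint
    root = Node()
    for nd in lineages:
        root.add_child(nd)
    return root


def sample_tree(ntaxa: int, branch_scale: float = 0.1, seed: int = 0) -> PhyloTree:
    """Random unrooted binary tree with exponential branch lengths.

    Leaf labels are ``T0001..``; every edge length is drawn i.i.d. from an
    exponential with mean ``branch_scale``. Reproducible given ``seed``.
    """
    if ntaxa < 4:
        raise ValueError("need at least 4 taxa for an unrooted binary tree")
    if branch_scale <= 0:
        raise ValueError("branch_scale must be positive")
    rng = np.random.default_rng(seed)
    labels = [f"T{i + 1:04d}" for i in range(ntaxa)]
    tree = PhyloTree(_random_join_topology(labels, rng))
    for nd in tree.postorder():
        if nd.parent is not None:
            nd.length = float(rng.exponential(branch_scale))
    return tree


@dataclass
class LGTScenario:
    """A lateral-transfer event: move ``focal_taxa`` onto ``donor_edge``.

    ``donor_edge`` is identified by the leaf set below the target edge of
    the focal-pruned species tree and must lie strictly inside one of the
    ``constraint_clades``.
    """

    species_tree: PhyloTree
    focal_taxa: frozenset
    donor_edge: frozenset
    constraint_clades: list = field(default_factory=list)

    def __post_init__(self):
        self.focal_taxa = frozenset(self.focal_taxa)
        self.donor_edge = frozenset(self.donor_edge)
        self.constraint_clades = [frozenset(c) for c in self.constraint_clades]

    def validate(self) -> None:
        if not self.species_tree.is_monophyletic(self.focal_taxa):
            raise InvalidCladeError("focal taxa are not a clade of the species tree")
        if self.focal_taxa & self.donor_edge:
            raise InvalidCladeError("donor edge overlaps the focal clade")
        scopes = [c for c in self.constraint_clades if self.donor_edge < c]
        if self.constraint_clades and not scopes:
            raise InvalidCladeError(
                "donor edge does not lie strictly inside any constraint clade"
            )
        for a in self.constraint_clades:
            for b in self.constraint_clades:
                if a is not b and a & b and not (a <= b or b <= a):
                    raise InvalidCladeError("constraint clades overlap improperly")


def build_lgt_gene_tree(scenario: LGTScenario) -> PhyloTree:
    """Prune the focal clade and regraft it at the midpoint of the donor
    edge (stem length = half the donor edge length).

    Raises
    ------
    DegenerateMoveError
        If the donor edge is where the clade already sits, so the "moved"
        tree would equal the species tree.
    """
    scenario.validate()
    focal_subtree, pruned, _ = extract_clade(
        scenario.species_tree, scenario.focal_taxa
    )
    below = pruned.clade_sets()
    target = None
    for nd, clade in below.items():
        if nd.parent is not None and clade == scenario.donor_edge:
            target = nd
            break
    if target is None:
        raise InvalidCladeError(
            "donor edge is not an edge of the focal-pruned species tree"
        )
    gene_tree = regraft(pruned, focal_subtree, target, stem_length=target.length / 2.0)
    if gene_tree.rf_distance(scenario.species_tree) == 0:
        raise DegenerateMoveError("donor edge is adjacent to the original stem")
    return gene_tree


def simulate_alignment(
    tree: PhyloTree,
    model: SubstModel,
    nsites: int,
    seed: int = 0,
    missing_fraction: float = 0.0,
) -> AminoAlignment:
    """Evolve independent columns down the tree.

    Root states are drawn from the stationary frequencies; each site is
    invariant with probability ``p_inv`` or assigned one of the k discrete
    gamma categories uniformly; branch transitions use exp(Q t r).
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if nsites < 1:
        raise ValueError("nsites must be positive")
    rng = np.random.default_rng(seed)
    rates = model.rates()
    k = len(rates)

    invariant = rng.random(nsites) < model.p_inv
    cat = rng.integers(0, k, size=nsites)
    cat[invariant] = k  # sentinel: zero-rate category

    pi = model.pi / model.pi.sum()
    root_states = rng.choice(20, size=nsites, p=pi)

    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    for nd in tree.preorder():
        if nd.parent is None:
            continue
        parent_states = states[id(nd.parent)]
        P = model.transition_matrices(nd.length, rates)  # (k, 20, 20)
        P = np.concatenate([P, np.eye(20)[None]], axis=0)  # invariant category
        probs = P[cat, parent_states, :]
        probs = probs / probs.sum(axis=1, keepdims=True)
        u = rng.random(nsites)
        child = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        states[id(nd)] = np.minimum(child, 19).astype(np.int64)

    labels = [nd.name for nd in leaves]
    matrix = np.vstack([states[id(nd)] for nd in leaves]).astype(np.int8)
    if missing_fraction > 0.0:
        mask = rng.random(matrix.shape) < missing_fraction
        matrix[mask] = MISSING
    return AminoAlignment(labels, matrix)


# -- GHF5-like gene-family bundles ----------------------------------------


@dataclass
class GHF5Params:
    """Sizes and model for a two-bacterial-subfamily + symbiont-clade
    gene family (defaults: 60 taxa x 300 sites)."""

    n_sf1: int = 22
    n_sf2: int = 22
    n_focal: int = 10
    n_outgroup: int = 6
    nsites: int = 300
    branch_scale: float = 0.06
    backbone_scale: float = 0.35
    model_spec: str = "WAG+G+I"
    alpha: float = 0.8
    p_inv: float = 0.1
    seed: int = 0

    @property
    def ntaxa(self) -> int:
        return self.n_sf1 + self.n_sf2 + self.n_focal + self.n_outgroup


@dataclass
class GHF5Bundle:
    alignment: AminoAlignment
    true_tree: PhyloTree
    focal_taxa: frozenset
    constraint_clades: list
    species_tree: PhyloTree
    scenario: LGTScenario | None
    model: SubstModel
    params: GHF5Params

    def __iter__(self):
        return iter(
            (self.alignment, self.true_tree, self.focal_taxa, self.constraint_clades)
        )


def _group_subtree(prefix: str, n: int, scale: float, rng: np.random.Generator) -> Node:
    labels = [f"{prefix}{i + 1:03d}" for i in range(n)]
    if n == 1:
        return Node(name=labels[0])
    lineages = [Node(name=l) for l in labels]
    while len(lineages) > 2:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        joint = Node()
        joint.add_child(lineages[i])
        joint.add_child(lineages[j])
        lineages[j:j + 1] = []
        lineages[i] = joint
    top = Node()
    for nd in lineages:
        top.add_child(nd)
    for sub in PhyloTree(top).postorder():
        if sub.parent is not None:
            sub.length = float(rng.exponential(scale))
    return top


def ghf5_like_bundle(params: GHF5Params | None = None, lgt: bool = True) -> GHF5Bundle:
    """Simulate one gene family with or without a lateral-transfer event.

    The species tree holds two "bacterial" subfamily clades (SF1*, SF2*),
    a focal "symbiont" clade (SYM*) and an outgroup (OUT*), the focal clade
    attaching outside both subfamilies. With ``lgt=True`` the gene tree
    nests the focal clade inside subfamily 1; otherwise the gene tree is
    the species tree (vertical descent).
    """
    params = params or GHF5Params()
    if params.n_sf1 < 2 or params.n_sf2 < 2 or params.n_focal < 2:
        raise ValueError("subfamilies and focal clade need at least 2 taxa each")
    rng = np.random.default_rng(params.seed)

    sf1 = _group_subtree("SF1_", params.n_sf1, params.branch_scale, rng)
    sf2 = _group_subtree("SF2_", params.n_sf2, params.branch_scale, rng)
    sym = _group_subtree("SYM_", params.n_focal, params.branch_scale, rng)
    out = _group_subtree("OUT_", params.n_outgroup, params.branch_scale, rng)
    root = Node()
    root.add_child(sf1)
    root.add_child(sf2)
    side = Node()
    side.add_child(sym)
    side.add_child(out)
    root.add_child(side)
    # backbone stems get a floor so the clades stay separated: a near-zero
    # stem would make the vertical and nested placements indistinguishable
    for stem in (sf1, sf2, sym, out, side):
        stem.length = params.backbone_scale * (0.6 + float(rng.exponential(0.4)))
    species_tree = PhyloTree(root)

    sets = species_tree.clade_sets()
    sf1_taxa, sf2_taxa = sets[sf1], sets[sf2]
    focal_taxa = sets[sym]
    # sub-sub-families: the two daughter clades of each subfamily root
    constraint_clades = [sets[c] for c in sf1.children if not c.is_leaf]
    constraint_clades += [sets[c] for c in sf2.children if not c.is_leaf]

    scenario = None
    if lgt:
        # donor edge: the larger daughter clade of subfamily 1
        donor = max(
            (sets[c] for c in sf1.children), key=lambda s: (len(s), sorted(s))
        )
        scenario = LGTScenario(
            species_tree=species_tree,
            focal_taxa=focal_taxa,
            donor_edge=donor,
            constraint_clades=[sf1_taxa, sf2_taxa],
        )
        true_tree = build_lgt_gene_tree(scenario)
    else:
        true_tree = species_tree.copy()

    model = parse_model_spec(
        params.model_spec, alpha=params.alpha, p_inv=params.p_inv
    )
    alignment = simulate_alignment(
        true_tree, model, params.nsites, seed=params.seed + 1
    )
    return GHF5Bundle(
        alignment=alignment,
        true_tree=true_tree,
        focal_taxa=focal_taxa,
        constraint_clades=constraint_clades,
        species_tree=species_tree,
        scenario=scenario,
        model=model,
        params=params,
    )
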