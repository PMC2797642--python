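import numpy as np
import pytest
from helpers import brute_force_regrafts, topology_key
from scipy.stats import binom, spearmanr

from lgtplace.phylo_core import MISSING, parse_model_spec
from lgtplace.synthetic_data import (
    GHF5Params,
    LGTScenario,
    build_lgt_gene_tree,
    ghf5_like_bundle,
    sample_tree,
    simulate_alignment,
)
from lgtplace.topology_moves import DegenerateMoveError, InvalidCladeError


class TestSampleTree:
    def test_quartet_combinatorics(self):
        tree = sample_tree(4, 0.1, seed=0)
        assert len(tree.leaves()) == 4
        assert tree.n_edges() == 5
        assert sum(1 for nd in tree.postorder() if not nd.is_leaf) == 2

    def test_determinism(self):
        a = sample_tree(64, 0.1, seed=1).to_newick()
        b = sample_tree(64, 0.1, seed=1).to_newick()
        assert a == b
        c = sample_tree(64, 0.1, seed=2).to_newick()
        assert a != c

    def test_rejects_tiny_trees(self):
        with pytest.raises(ValueError):
            sample_tree(3, 0.1, seed=0)

    def test_branch_lengths_exponential_mean(self):
        # Monte-Carlo check of the stated exponential(branch_scale) law
        scale = 0.13
        lengths = []
        for seed in range(3000):
            t = sample_tree(8, scale, seed=seed)
            lengths.extend(nd.length for nd in t.postorder() if nd.parent)
        assert abs(np.mean(lengths) - scale) / scale < 0.02

    def test_labels_are_padded(self):
        names = sample_tree(12, 0.1, seed=3).leaf_names()
        assert sorted(names) == [f"T{i:04d}" for i in range(1, 13)]


class TestSimulateAlignment:
    def test_zero_branch_lengths_copy_root(self, poisson_model):
        tree = sample_tree(6, 0.1, seed=4)
        for nd in tree.postorder():
            nd.length = 0.0
        aln = simulate_alignment(tree, poisson_model, 200, seed=5)
        assert all(np.array_equal(aln.states[0], row) for row in aln.states)

    def test_root_frequencies_match_stationary(self, poisson_model):
        # all-zero branch lengths expose the root draw at every leaf
        tree = sample_tree(4, 0.1, seed=6)
        for nd in tree.postorder():
            nd.length = 0.0
        n = 20_000
        aln = simulate_alignment(tree, poisson_model, n, seed=7)
        counts = np.bincount(aln.states[0], minlength=20)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.05)
        assert np.all(counts >= lo) and np.all(counts <= hi)

    def test_two_taxon_difference_fraction_closed_form(self, poisson_model):
        from lgtplace.phylo_core import PhyloTree

        t = 0.5
        n = 20_000
        tree = PhyloTree.from_newick(f"(A:{t},B:0.0);")
        aln = simulate_alignment(tree, poisson_model, n, seed=8)
        p_expected = 1.0 - (1.0 / 20.0 + (19.0 / 20.0) * np.exp(-(20.0 / 19.0) * t))
        ndiff = int((aln.states[0] != aln.states[1]).sum())
        lo, hi = binom.ppf([0.005, 0.995], n, p_expected)
        assert lo <= ndiff <= hi

    def test_determinism_and_seed_sensitivity(self, wag_gi_model):
        tree = sample_tree(8, 0.2, seed=9)
        a = simulate_alignment(tree, wag_gi_model, 100, seed=10).to_fasta()
        b = simulate_alignment(tree, wag_gi_model, 100, seed=10).to_fasta()
        c = simulate_alignment(tree, wag_gi_model, 100, seed=11).to_fasta()
        assert a == b
        assert a != c

    def test_only_canonical_residues_without_masking(self, wag_gi_model):
        tree = sample_tree(10, 0.2, seed=12)
        aln = simulate_alignment(tree, wag_gi_model, 150, seed=13)
        assert aln.states.max() < MISSING

    def test_missing_fraction_masks_cells(self, wag_gi_model):
        tree = sample_tree(10, 0.2, seed=12)
        aln = simulate_alignment(
            tree, wag_gi_model, 400, seed=13, missing_fraction=0.1
        )
        frac = (aln.states == MISSING).mean()
        assert 0.05 < frac < 0.15

    def test_pairwise_identity_decreases_with_path_length(self):
        tree = sample_tree(30, 0.08, seed=14)
        model = parse_model_spec("WAG+G", alpha=1.0)
        aln = simulate_alignment(tree, model, 500, seed=15)

        # path lengths via node depths from the structural root
        depth = {id(tree.root): 0.0}
        parent = {}
        for nd in tree.preorder():
            for c in nd.children:
                depth[id(c)] = depth[id(nd)] + c.length
                parent[id(c)] = nd
        leaves = tree.leaves()

        def path(a, b):
            seen = {}
            nd = a
            while nd is not None:
                seen[id(nd)] = depth[id(nd)]
                nd = parent.get(id(nd))
            nd = b
            while id(nd) not in seen:
                nd = parent[id(nd)]
            return depth[id(a)] + depth[id(b)] - 2 * depth[id(nd)]

        rng = np.random.default_rng(16)
        dists, idents = [], []
        for _ in range(100):
            i, j = rng.choice(len(leaves), 2, replace=False)
            dists.append(path(leaves[i], leaves[j]))
            ri, rj = aln.row(leaves[i].name), aln.row(leaves[j].name)
            idents.append(float((ri == rj).mean()))
        rho, _ = spearmanr(dists, idents)
        assert rho < 0


class TestBuildLgtGeneTree:
    @staticmethod
    def _scenario(seed=20):
        tree = sample_tree(10, 0.2, seed=seed)
        sets = {
            frozenset(c)
            for nd, c in tree.clade_sets().items()
            if nd.parent is not None and 2 <= len(c) <= 3
        }
        focal = sorted(sets, key=lambda s: sorted(s))[0]
        pruned_clades = [
            s for s in sorted(sets, key=lambda s: sorted(s)) if not (s & focal)
        ]
        donor = pruned_clades[0]
        return tree, focal, donor

    def test_graft_creates_nested_monophyly(self):
        tree, focal, donor = self._scenario()
        scen = LGTScenario(tree, focal, donor_edge=donor, constraint_clades=[])
        gene = build_lgt_gene_tree(scen)
        assert gene.is_monophyletic(focal | donor)
        assert gene.is_monophyletic(focal)
        assert gene.rf_distance(tree) > 0

    def test_matches_brute_force_regraft_oracle(self):
        tree, focal, donor = self._scenario(seed=23)
        scen = LGTScenario(tree, focal, donor_edge=donor, constraint_clades=[])
        gene = build_lgt_gene_tree(scen)
        oracle_keys = brute_force_regrafts(tree.to_newick(), set(focal))
        gene_key = topology_key(gene.to_newick())
        assert gene_key in oracle_keys
        # and it is the unique regraft nesting focal with exactly the donor clade
        assert gene.is_monophyletic(focal | donor)

    def test_degenerate_move_rejected(self):
        tree = sample_tree(8, 0.2, seed=24)
        sets = tree.clade_sets()
        focal = next(
            frozenset(c)
            for nd, c in sets.items()
            if nd.parent is not None and len(c) == 2
        )
        # regrafting onto the complement edge of the original stem is degenerate
        from lgtplace.topology_moves import extract_clade

        _, pruned, stem = extract_clade(tree, focal)
        donor = frozenset(pruned.clade_sets()[stem])
        scen = LGTScenario(tree, focal, donor_edge=donor, constraint_clades=[])
        with pytest.raises((DegenerateMoveError, InvalidCladeError)):
            build_lgt_gene_tree(scen)

    def test_scenario_validation(self):
        tree, focal, donor = self._scenario(seed=25)
        with pytest.raises(InvalidCladeError):
            LGTScenario(
                tree, focal, donor_edge=donor, constraint_clades=[donor]
            ).validate()  # donor not STRICTLY inside the constraint clade
        bad_focal = frozenset(list(focal)[:1] + ["T0009"])
        scen = LGTScenario(tree, bad_focal, donor_edge=donor, constraint_clades=[])
        if not tree.is_monophyletic(bad_focal):
            with pytest.raises(InvalidCladeError):
                scen.validate()


class TestGhf5Bundle:
    def test_lgt_true_nests_focal_inside_subfamily_one(self):
        bundle = ghf5_like_bundle(GHF5Params(seed=1), lgt=True)
        sf1 = {l for l in bundle.true_tree.leaf_names() if l.startswith("SF1_")}
        assert bundle.true_tree.is_monophyletic(sf1 | bundle.focal_taxa)
        assert bundle.true_tree.is_monophyletic(bundle.focal_taxa)

    def test_lgt_false_keeps_focal_outside_subfamilies(self):
        bundle = ghf5_like_bundle(GHF5Params(seed=1), lgt=False)
        names = bundle.true_tree.leaf_names()
        for prefix in ("SF1_", "SF2_"):
            sub = {l for l in names if l.startswith(prefix)}
            assert bundle.true_tree.is_monophyletic(sub)
            assert not bundle.true_tree.is_monophyletic(sub | bundle.focal_taxa) or (
                len(sub | bundle.focal_taxa) == len(names)
            )

    def test_default_dimensions(self):
        bundle = ghf5_like_bundle(GHF5Params(seed=2), lgt=True)
        assert bundle.alignment.ntaxa == 60
        assert bundle.alignment.nsites == 300

    def test_unpacks_as_four_tuple(self):
        aln, tree, focal, clades = ghf5_like_bundle(GHF5Params(seed=3), lgt=False)
        assert aln.ntaxa == len(tree.leaves())
        assert focal <= tree.leaf_set()
        assert all(c <= tree.leaf_set() for c in clades)

    def test_determinism(self):
        a = ghf5_like_bundle(GHF5Params(seed=4), lgt=True)
        b = ghf5_like_bundle(GHF5Params(seed=4), lgt=True)
        assert a.alignment.to_fasta() == b.alignment.to_fasta()
        assert a.true_tree.to_newick() == b.true_tree.to_newick()
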