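import numpy as np
import pytest
from helpers import exhaustive_sh_pvalues

from lgtplace.phylo_core import parse_model_spec, site_loglikelihoods
from lgtplace.synthetic_data import sample_tree, simulate_alignment
from lgtplace.topology_moves import enumerate_placements
from lgtplace.topology_test import (
    SiteLoglikMatrix,
    per_topology_site_ll,
    read_report,
    rell_bootstrap,
    sh_test,
    write_report,
)


@pytest.fixture(scope="module")
def eval_case():
    tree = sample_tree(8, 0.2, seed=81)
    model = parse_model_spec("WAG+G", alpha=0.9)
    aln = simulate_alignment(tree, model, 120, seed=82)
    clade = next(
        frozenset(c)
        for nd, c in tree.clade_sets().items()
        if nd.parent is not None and len(c) == 2
    )
    topo_set = enumerate_placements(tree, clade)
    return tree, aln, model, topo_set


class TestPerTopologySiteLL:
    def test_fixed_mode_is_passthrough(self, eval_case):
        tree, aln, model, _ = eval_case
        matrix = per_topology_site_ll([tree, tree], aln, model, reopt="fixed")
        direct = site_loglikelihoods(tree, aln, model)
        assert np.array_equal(matrix.matrix[0], direct)
        assert np.array_equal(matrix.matrix[1], direct)

    def test_duplicate_base_row_matches_base(self, eval_case):
        tree, aln, model, _ = eval_case
        matrix = per_topology_site_ll(
            [tree, tree.copy()], aln, model, reopt="branches", tol=1e-4
        )
        assert np.abs(matrix.matrix[0] - matrix.matrix[1]).max() < 1e-6

    def test_true_topology_has_highest_total(self, eval_case):
        tree, aln, model, topo_set = eval_case
        matrix = per_topology_site_ll(topo_set, aln, model, reopt="branches")
        assert int(np.argmax(matrix.totals)) == 0  # base tree is the truth

    def test_totals_equal_row_sums(self, eval_case):
        tree, aln, model, _ = eval_case
        matrix = per_topology_site_ll([tree, tree], aln, model, reopt="fixed")
        assert np.allclose(matrix.totals, matrix.matrix.sum(axis=1), atol=1e-8)

    def test_bad_mode_rejected(self, eval_case):
        tree, aln, model, _ = eval_case
        with pytest.raises(ValueError):
            per_topology_site_ll([tree], aln, model, reopt="magic")

    def test_errors_carry_topology_id(self, eval_case):
        tree, aln, model, _ = eval_case
        broken = tree.copy()
        broken.find_leaf(broken.leaf_names()[0]).name = "NOT_IN_ALN"
        with pytest.raises(RuntimeError, match="Tree: 1"):
            per_topology_site_ll([tree, broken], aln, model, reopt="fixed")


class TestRellBootstrap:
    def test_single_site_degenerate(self):
        M = SiteLoglikMatrix(ids=["a", "b"], matrix=[[-1.5], [-2.0]])
        reps = rell_bootstrap(M, B=50, seed=0)
        assert np.allclose(reps[:, 0], -1.5)
        assert np.allclose(reps[:, 1], -2.0)

    def test_replicates_are_weighted_totals(self, rng):
        M = SiteLoglikMatrix(
            ids=["a", "b"], matrix=rng.normal(-3, 1, size=(2, 40))
        )
        reps = rell_bootstrap(M, B=200, seed=1)
        # every replicate must be expressible as integer site weights
        # summing to nsites => bounded by nsites * (min, max) per topology
        assert reps.shape == (200, 2)
        for a in range(2):
            assert reps[:, a].min() >= 40 * M.matrix[a].min() - 1e-9
            assert reps[:, a].max() <= 40 * M.matrix[a].max() + 1e-9

    def test_unbiased_for_totals(self, rng):
        M = SiteLoglikMatrix(ids=["a", "b"], matrix=rng.normal(-3, 1, size=(2, 30)))
        reps = rell_bootstrap(M, B=10_000, seed=2)
        site_var = M.matrix.var(axis=1, ddof=0)
        se = np.sqrt(30 * site_var / 10_000)
        assert np.all(np.abs(reps.mean(axis=0) - M.totals) < 3 * se)

    def test_seeded_reproducibility(self, rng):
        M = SiteLoglikMatrix(ids=["a", "b"], matrix=rng.normal(-3, 1, size=(2, 25)))
        assert np.array_equal(
            rell_bootstrap(M, B=64, seed=7), rell_bootstrap(M, B=64, seed=7)
        )

    def test_invalid_replicate_count(self):
        M = SiteLoglikMatrix(ids=["a", "b"], matrix=[[-1.0], [-1.0]])
        with pytest.raises(ValueError):
            rell_bootstrap(M, B=0)


class TestShTest:
    def test_identical_rows_never_rejected(self):
        row = np.full(20, -2.3)
        M = SiteLoglikMatrix(ids=["a", "b", "c"], matrix=np.vstack([row] * 3))
        report = sh_test(M, B=200, seed=3)
        for r in report.rows:
            assert r.d_lh == 0.0
            assert r.p_value == 1.0
            assert not r.significantly_worse

    def test_best_tree_semantics(self, rng):
        M = SiteLoglikMatrix(
            ids=["best", "worse"],
            matrix=np.vstack([rng.normal(-2, 0.5, 60), rng.normal(-2.5, 0.5, 60)]),
        )
        report = sh_test(M, B=500, seed=4)
        best = report.rows[report.best_index]
        assert best.d_lh == 0.0
        assert not best.significantly_worse
        assert best.p_value == pytest.approx(1.0, abs=0.01)
        other = [r for r in report.rows if r is not best][0]
        assert other.d_lh <= 0.0
        assert other.sd >= 0.0

    def test_matches_exhaustive_rell_oracle(self):
        M = SiteLoglikMatrix(
            ids=["t1", "t2"],
            matrix=np.array([[-1.0, -2.0, -1.5], [-1.4, -1.7, -1.9]]),
        )
        exact = exhaustive_sh_pvalues(M.matrix)
        report = sh_test(M, B=20_000, seed=5)
        for r, p_exact in zip(report.rows, exact):
            se = np.sqrt(p_exact * (1 - p_exact) / 20_000) + 1e-4
            assert abs(r.p_value - p_exact) < 4 * se + 1e-3

    def test_pvalues_monotone_in_likelihood_difference(self, rng):
        base = rng.normal(-3, 1, size=80)
        rows = [base, base - 0.01, base - 0.05, base - 0.2]
        M = SiteLoglikMatrix(ids=[f"t{i}" for i in range(4)], matrix=np.vstack(rows))
        report = sh_test(M, B=2000, seed=6)
        ds = [-r.d_lh for r in report.rows]
        ps = [r.p_value for r in report.rows]
        order = np.argsort(ds)
        assert all(
            ps[order[i]] >= ps[order[i + 1]] - 1e-12 for i in range(len(ps) - 1)
        )

    def test_invariant_under_topology_reordering(self, rng):
        M = rng.normal(-3, 1, size=(3, 50))
        r1 = sh_test(SiteLoglikMatrix(ids=["a", "b", "c"], matrix=M), B=800, seed=7)
        perm = [2, 0, 1]
        r2 = sh_test(
            SiteLoglikMatrix(ids=["c", "a", "b"], matrix=M[perm]), B=800, seed=7
        )
        by_id_1 = {r.tree_id: r for r in r1.rows}
        by_id_2 = {r.tree_id: r for r in r2.rows}
        for tid in "abc":
            assert by_id_1[tid].p_value == by_id_2[tid].p_value
            assert by_id_1[tid].d_lh == pytest.approx(by_id_2[tid].d_lh)

    def test_parameter_validation(self, rng):
        M = SiteLoglikMatrix(ids=["a", "b"], matrix=rng.normal(-3, 1, size=(2, 10)))
        with pytest.raises(ValueError):
            sh_test(M, B=0)
        with pytest.raises(ValueError):
            sh_test(SiteLoglikMatrix(ids=["a"], matrix=M.matrix[:1]), B=10)


class TestWriteReport:
    def test_round_trip(self, tmp_path, rng):
        M = SiteLoglikMatrix(ids=["a", "b", "c"], matrix=rng.normal(-3, 1, (3, 40)))
        report = sh_test(M, B=300, seed=8)
        path = tmp_path / "report.tsv"
        write_report(report, path)
        back = read_report(path)
        assert list(back.columns) == [
            "Tree", "Likelihood", "D_LH", "SD", "p_value", "SignificantlyWorse",
        ]
        by_id = {r.tree_id: r for r in report.rows}
        for _, row in back.iterrows():
            assert row["Likelihood"] == pytest.approx(
                by_id[row["Tree"]].loglik, abs=1e-6
            )
            assert row["p_value"] == pytest.approx(
                by_id[row["Tree"]].p_value, abs=1e-6
            )

    def test_best_first_then_input_order(self, tmp_path, rng):
        M = np.vstack(
            [rng.normal(-3.5, 1, 30), rng.normal(-3.0, 1, 30), rng.normal(-4.0, 1, 30)]
        )
        report = sh_test(SiteLoglikMatrix(ids=["x", "y", "z"], matrix=M), B=100, seed=9)
        path = tmp_path / "report.tsv"
        write_report(report, path)
        back = read_report(path)
        best_id = report.rows[report.best_index].tree_id
        assert back.iloc[0]["Tree"] == best_id
        rest = [t for t in ["x", "y", "z"] if t != best_id]
        assert list(back["Tree"])[1:] == rest

    def test_flag_domain(self, tmp_path, rng):
        M = SiteLoglikMatrix(ids=["a", "b"], matrix=rng.normal(-3, 1, (2, 20)))
        path = tmp_path / "report.tsv"
        write_report(sh_test(M, B=100, seed=10), path)
        flags = set(read_report(path)["SignificantlyWorse"])
        assert flags <= {"Yes", "No"}
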