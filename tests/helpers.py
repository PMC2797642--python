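"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's own pruning/regraft code paths:
likelihoods come from exhaustive internal-state enumeration, tree
comparisons and regraft enumeration go through dendropy, gamma category
means come from numerical quadrature, and SH p-values from exhaustive
multinomial enumeration.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from lgtplace.phylo_core import MISSING


def brute_site_loglik(tree, aln, model) -> np.ndarray:
    """Exact site log-likelihoods by summing over every assignment of
    states to internal nodes (vectorized; feasible for <= 5 taxa)."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    idx = {id(n): i for i, n in enumerate(internal)}
    assigns = np.indices((20,) * len(internal)).reshape(len(internal), -1)
    leaf_rows = {id(n): aln.row(n.name) for n in nodes if n.is_leaf}
    rates = model.rates()
    ns = aln.nsites
    lvar = np.zeros((len(rates), ns))
    for c, r in enumerate(rates):
        P = {
            id(n): model.transition_matrix(n.length * r)
            for n in nodes
            if n.parent is not None
        }
        for s in range(ns):
            prod = model.pi[assigns[idx[id(tree.root)]]].copy()
            for n in nodes:
                if n.parent is None:
                    continue
                pa = assigns[idx[id(n.parent)]]
                if n.is_leaf:
                    st = leaf_rows[id(n)][s]
                    if st < MISSING:
                        prod = prod * P[id(n)][pa, st]
                else:
                    prod = prod * P[id(n)][pa, assigns[idx[id(n)]]]
            lvar[c, s] = prod.sum()
    Lvar = lvar.mean(axis=0)
    pv = model.p_inv
    mat = np.vstack([leaf_rows[id(n)] for n in nodes if n.is_leaf])
    inv = np.zeros(ns)
    for s in range(ns):
        col = mat[:, s]
        resid = np.unique(col[col < MISSING])
        if resid.size == 0:
            inv[s] = 1.0
        elif resid.size == 1:
            inv[s] = model.pi[resid[0]]
    return np.log((1.0 - pv) * Lvar + pv * inv)


def gamma_bin_means_quadrature(alpha: float, k: int) -> np.ndarray:
    """Category means of Gamma(alpha, alpha) over its k equal-mass bins,
    via numerical integration of x * pdf(x)."""
    edges = np.concatenate(
        [[0.0], gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha), [np.inf]]
    )
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = quad(
            lambda x: x * gamma_dist.pdf(x, alpha, scale=1.0 / alpha),
            lo,
            min(hi, gamma_dist.ppf(1.0 - 1e-14, alpha, scale=1.0 / alpha)),
            limit=200,
        )
        means.append(val * k)
    return np.asarray(means)


# -- dendropy-based tree oracles ------------------------------------------


def dendropy_rf(newick1: str, newick2: str) -> int:
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


def _dendropy_unrooted(newick: str, tns) -> dendropy.Tree:
    t = dendropy.Tree.get(
        data=newick, schema="newick", taxon_namespace=tns, preserve_underscores=True
    )
    t.is_rooted = False
    t.update_bipartitions(suppress_unifurcations=True)
    return t


def brute_force_regrafts(base_newick: str, focal: set) -> list:
    """All distinct unrooted topologies obtained by pruning the focal clade
    and reattaching it on every edge of the remainder, excluding the base
    topology. Returns bipartition-set keys (frozensets of leaf frozensets).

    Implemented entirely with dendropy node surgery.
    """
    tns = dendropy.TaxonNamespace()
    base = _dendropy_unrooted(base_newick, tns)
    base_key = topology_key(base_newick)
    rest = [l.taxon.label for l in base.leaf_node_iter() if l.taxon.label not in focal]

    pruned = _dendropy_unrooted(base_newick, tns)
    pruned.retain_taxa_with_labels(rest)
    pruned.update_bipartitions(suppress_unifurcations=True)
    pruned_newick = pruned.as_string(schema="newick", suppress_rooting=True)

    focal_tree = _dendropy_unrooted(base_newick, tns)
    focal_tree.retain_taxa_with_labels(sorted(focal))
    focal_newick = focal_tree.as_string(schema="newick", suppress_rooting=True)

    seen = set()
    out = []
    n_edges = sum(1 for nd in _dendropy_unrooted(pruned_newick, tns).preorder_node_iter() if nd.parent_node is not None)
    for i in range(n_edges):
        work = dendropy.Tree.get(
            data=pruned_newick, schema="newick", taxon_namespace=tns,
            preserve_underscores=True,
        )
        work.is_rooted = False
        target = [nd for nd in work.preorder_node_iter() if nd.parent_node is not None][i]
        parent = target.parent_node
        joint = parent.new_child()
        parent.remove_child(target)
        joint.add_child(target)
        graft = dendropy.Tree.get(
            data=focal_newick, schema="newick", taxon_namespace=tns,
            preserve_underscores=True,
        )
        joint.add_child(graft.seed_node)
        work.update_bipartitions(suppress_unifurcations=True)
        key = topology_key(work.as_string(schema="newick", suppress_rooting=True))
        if key != base_key and key not in seen:
            seen.add(key)
            out.append(key)
    return out


def topology_key(newick: str) -> frozenset:
    """Canonical unrooted-topology key: frozenset of non-trivial
    bipartition leaf sets (side not containing the smallest label)."""
    tns = dendropy.TaxonNamespace()
    t = _dendropy_unrooted(newick, tns)
    labels = sorted(l.taxon.label for l in t.leaf_node_iter())
    ref = labels[0]
    full = frozenset(labels)
    key = set()
    for edge in t.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        below = frozenset(
            l.taxon.label for l in edge.head_node.leaf_iter()
        )
        if len(below) < 2 or len(below) > len(full) - 2:
            continue
        side = full - below if ref in below else below
        key.add(side)
    return frozenset(key)


# -- exhaustive SH oracle --------------------------------------------------


def compositions(total: int, cells: int):
    """All non-negative integer vectors of the given length summing to
    ``total`` (stars and bars)."""
    for cuts in itertools.combinations(range(total + cells - 1), cells - 1):
        prev = -1
        vec = []
        for c in cuts:
            vec.append(c - prev - 1)
            prev = c
        vec.append(total + cells - 2 - prev)
        yield tuple(vec)


def exhaustive_sh_pvalues(M: np.ndarray) -> np.ndarray:
    """Exact SH p-values (without finite-sample correction) by enumerating
    every multinomial site-weight vector; centering uses the exact
    expectation of the resampled totals."""
    M = np.asarray(M, dtype=float)
    ntopo, ns = M.shape
    totals = M.sum(axis=1)
    D_obs = totals.max() - totals
    p = np.zeros(ntopo)
    logfact = [math.lgamma(i + 1) for i in range(ns + 1)]
    for w in compositions(ns, ns):
        logprob = logfact[ns] - sum(logfact[x] for x in w) + ns * math.log(1.0 / ns)
        prob = math.exp(logprob)
        L = M @ np.asarray(w, dtype=float)
        R = L - totals
        D_null = R.max() - R
        p += prob * (D_null >= D_obs - 1e-12)
    return np.clip(p, 0.0, 1.0)
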