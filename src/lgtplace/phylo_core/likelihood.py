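"""Pruning likelihood for amino-acid alignments with gamma + invariant-site
rate mixtures, plus cached-message branch-length optimization.

Partial likelihoods are kept per rate category with per-node, per-site log
scalers so deep trees do not underflow. Branch optimization walks the tree
once per sweep, optimizing each edge against cached partials on both sides;
partials below an edge are refreshed on the way back up so every
one-dimensional optimization sees the exact likelihood.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import MISSING, AminoAlignment
from .models import SubstModel
from .tree import Node, PhyloTree

MIN_BLEN = 1e-8
MAX_BLEN = 10.0


class MissingTaxonError(KeyError):
    pass


class NumericalFailureError(ArithmeticError):
    pass


class TreeLikelihood:
    """Likelihood engine bound to one (tree, alignment, model) triple.

    The tree is used in place: ``optimize_branches`` writes optimized
    lengths back onto the tree's nodes.
    """

    def __init__(self, tree: PhyloTree, aln: AminoAlignment, model: SubstModel):
        self.tree = tree
        self.aln = aln
        self.model = model
        self.nodes: list[Node] = list(tree.postorder())
        self._index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.children = [
            [self._index[id(c)] for c in nd.children] for nd in self.nodes
        ]
        self.nsites = aln.nsites
        k = model.k if model.alpha is not None else 1
        self.k = k

        label_to_row = {l: r for l, r in zip(aln.labels, aln.states)}
        self._leaf_partial: dict[int, np.ndarray] = {}
        leaf_rows = {}
        for i, nd in enumerate(self.nodes):
            if not nd.is_leaf:
                continue
            if nd.name not in label_to_row:
                raise MissingTaxonError(f"tree leaf {nd.name!r} has no alignment row")
            row = label_to_row[nd.name]
            part = np.zeros((self.nsites, 20))
            obs = row < MISSING
            part[np.arange(self.nsites)[obs], row[obs]] = 1.0
            part[~obs, :] = 1.0
            self._leaf_partial[i] = part
            leaf_rows[i] = row

        # invariant-category site likelihoods: pi of the single observed
        # residue, 1.0 if every state is missing, 0 for variable columns
        rows = np.vstack([leaf_rows[i] for i in sorted(leaf_rows)])
        self._inv_lik = np.zeros(self.nsites)
        for s in range(self.nsites):
            col = rows[:, s]
            residues = np.unique(col[col < MISSING])
            if residues.size == 0:
                self._inv_lik[s] = 1.0
            elif residues.size == 1:
                self._inv_lik[s] = model.pi[residues[0]]

        n = len(self.nodes)
        self._inside: list[np.ndarray | None] = [None] * n
        self._scal: list[np.ndarray | None] = [None] * n
        self._msg_up: list[np.ndarray | None] = [None] * n

    # -- core passes -------------------------------------------------------

    def _pmats(self, t: float) -> np.ndarray:
        return self.model.transition_matrices(t, self.model.rates())

    def _refresh_node(self, i: int) -> None:
        """Recompute inside partial (and up message) of node i from its
        children's current messages."""
        nd = self.nodes[i]
        if nd.is_leaf:
            self._inside[i] = np.broadcast_to(
                self._leaf_partial[i], (self.k, self.nsites, 20)
            )
            self._scal[i] = np.zeros(self.nsites)
        else:
            prod = np.ones((self.k, self.nsites, 20))
            scal = np.zeros(self.nsites)
            for c in self.children[i]:
                prod = prod * self._msg_up[c]
                scal += self._scal[c]
            factor = prod.max(axis=(0, 2))
            factor[factor == 0.0] = 1.0
            prod /= factor[None, :, None]
            self._inside[i] = prod
            self._scal[i] = scal + np.log(factor)
        if nd.parent is not None:
            P = self._pmats(nd.length)
            self._msg_up[i] = self._inside[i] @ P.transpose(0, 2, 1)

    def full_pass(self) -> None:
        for i in range(len(self.nodes)):
            self._refresh_node(i)

    def _combine(self, var_mean: np.ndarray, scal: np.ndarray) -> np.ndarray:
        """Mix the variable-rate likelihood (scaled by exp(scal)) with the
        invariant category into per-site log-likelihoods."""
        with np.errstate(divide="ignore"):
            lv = np.log(var_mean) + scal
            p = self.model.p_inv
            if p == 0.0:
                return lv
            li = np.log(p * self._inv_lik)
        return np.logaddexp(np.log1p(-p) + lv, li)

    def site_loglik(self) -> np.ndarray:
        """Per-site natural-log likelihoods (runs a full post-order pass)."""
        self.full_pass()
        r = len(self.nodes) - 1
        site_var = (self._inside[r] @ self.model.pi).mean(axis=0)
        ll = self._combine(site_var, self._scal[r])
        if not np.all(np.isfinite(ll)):
            raise NumericalFailureError("non-finite site log-likelihood")
        return ll

    def loglik(self) -> float:
        return float(self.site_loglik().sum())

    # -- branch optimization ----------------------------------------------

    def _edge_loglik(self, out, out_scal, inside_v, scal_v, P) -> float:
        msg = inside_v @ P.transpose(0, 2, 1)
        site_var = (out * msg).sum(axis=2).mean(axis=0)
        return float(self._combine(site_var, out_scal + scal_v).sum())

    def _optimize_edge(self, v: int, out, out_scal) -> None:
        inside_v, scal_v = self._inside[v], self._scal[v]
        nd = self.nodes[v]

        def neg(t: float) -> float:
            return -self._edge_loglik(out, out_scal, inside_v, scal_v, self._pmats(t))

        current = neg(nd.length)
        res = minimize_scalar(
            neg,
            bounds=(MIN_BLEN, MAX_BLEN),
            method="bounded",
            options={"xatol": self._xatol, "maxiter": 60},
        )
        if np.isfinite(res.fun) and res.fun <= current:
            nd.length = float(res.x)
        P = self._pmats(nd.length)
        self._msg_up[v] = inside_v @ P.transpose(0, 2, 1)

    def _smooth(self, u: int, out_u: np.ndarray, out_scal_u: np.ndarray) -> None:
        kids = self.children[u]
        for v in kids:
            sib = out_u.copy()
            sib_scal = out_scal_u.copy()
            for w in kids:
                if w != v:
                    sib *= self._msg_up[w]
                    sib_scal += self._scal[w]
            factor = sib.max(axis=(0, 2))
            factor[factor == 0.0] = 1.0
            sib /= factor[None, :, None]
            sib_scal += np.log(factor)

            self._optimize_edge(v, sib, sib_scal)
            if self.children[v]:
                P = self._pmats(self.nodes[v].length)
                out_v = sib @ P  # message crossing the edge towards v
                self._smooth(v, out_v, sib_scal)
                self._refresh_node(v)

    def optimize_branches(self, tol: float = 1e-4, max_sweeps: int = 20) -> float:
        """Coordinate-ascent branch-length optimization; returns the final
        total log-likelihood. Non-decreasing across sweeps by construction
        (each 1-D step only moves if it improves the exact likelihood)."""
        ll = self.loglik()
        root = len(self.nodes) - 1
        prior = np.broadcast_to(self.model.pi, (self.k, self.nsites, 20))
        # per-edge bracket precision scales with the requested lnL tolerance
        self._xatol = max(1e-7, min(3e-4, tol))
        for _ in range(max_sweeps):
            self._smooth(root, prior, np.zeros(self.nsites))
            new_ll = self.loglik()
            if not np.isfinite(new_ll):
                raise NumericalFailureError("branch optimization produced non-finite lnL")
            if new_ll - ll < tol:
                ll = max(ll, new_ll)
                break
            ll = new_ll
        return ll


def site_loglikelihoods(
    tree: PhyloTree, aln: AminoAlignment, model: SubstModel
) -> np.ndarray:
    """Per-site log-likelihoods of ``aln`` on ``tree`` under ``model``.

    Missing states contribute all-ones partials; the invariant-site category
    follows the standard +I definition (zero likelihood for variable
    columns).
    """
    if not all(np.isfinite(nd.length) for nd in tree.postorder() if nd.parent):
        raise ValueError("non-finite branch length")
    return TreeLikelihood(tree, aln, model).site_loglik()


def optimize_branch_lengths(
    tree: PhyloTree,
    aln: AminoAlignment,
    model: SubstModel,
    tol: float = 1e-4,
    max_sweeps: int = 20,
) -> tuple[PhyloTree, float]:
    """Optimize all branch lengths of ``tree`` in place (bounded per-branch
    search in [1e-8, 10]); returns ``(tree, final log-likelihood)``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    engine = TreeLikelihood(tree, aln, model)
    ll = engine.optimize_branches(tol=tol, max_sweeps=max_sweeps)
    return tree, ll
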