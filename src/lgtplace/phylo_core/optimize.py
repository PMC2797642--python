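"""Rate-parameter fitting and information-criterion model selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .alignment import AminoAlignment
from .likelihood import NumericalFailureError, TreeLikelihood
from .models import SubstModel, parse_model_spec
from .tree import PhyloTree

ALPHA_BOUNDS = (0.02, 100.0)
PINV_BOUNDS = (0.0, 0.99)


def optimize_rate_params(
    tree: PhyloTree, aln: AminoAlignment, model: SubstModel
) -> tuple[SubstModel, float]:
    """Fit gamma shape (and invariant proportion when the model carries +I)
    by bounded optimization at fixed branch lengths.

    Returns the refitted model and its log-likelihood; the result never has
    a lower likelihood than the input model.
    """
    fit_alpha = model.alpha is not None
    fit_pinv = getattr(model, "fit_pinv", False)

    def loglik_of(m: SubstModel) -> float:
        return TreeLikelihood(tree, aln, m).loglik()

    start_ll = loglik_of(model)
    if not fit_alpha and not fit_pinv:
        return model, start_ll

    if fit_alpha and not fit_pinv:
        res = minimize_scalar(
            lambda a: -loglik_of(model.with_params(alpha=float(a))),
            bounds=ALPHA_BOUNDS,
            method="bounded",
            options={"xatol": 1e-4},
        )
        best = model.with_params(alpha=float(res.x))
        best_ll = -float(res.fun)
    elif fit_pinv and not fit_alpha:
        res = minimize_scalar(
            lambda p: -loglik_of(model.with_params(p_inv=float(p))),
            bounds=PINV_BOUNDS,
            method="bounded",
            options={"xatol": 1e-5},
        )
        best = model.with_params(p_inv=float(res.x))
        best_ll = -float(res.fun)
    else:
        def neg(x: np.ndarray) -> float:
            return -loglik_of(model.with_params(alpha=float(x[0]), p_inv=float(x[1])))

        x0 = np.array([model.alpha, model.p_inv])
        res = minimize(
            neg,
            x0,
            method="L-BFGS-B",
            bounds=[ALPHA_BOUNDS, PINV_BOUNDS],
            options={"maxiter": 60},
        )
        best = model.with_params(alpha=float(res.x[0]), p_inv=float(res.x[1]))
        best_ll = -float(res.fun)

    if not np.isfinite(best_ll):
        raise NumericalFailureError("rate-parameter fit produced non-finite lnL")
    if best_ll < start_ll:
        return model, start_ll
    return best, best_ll


def fit_model(
    tree: PhyloTree,
    aln: AminoAlignment,
    model: SubstModel,
    tol: float = 1e-4,
    max_cycles: int = 20,
    branch_sweeps_per_cycle: int = 1,
) -> tuple[PhyloTree, SubstModel, float]:
    """Alternate one branch-length sweep with one rate-parameter fit until
    the log-likelihood gain falls below ``tol`` (branch lengths updated in
    place)."""
    ll = TreeLikelihood(tree, aln, model).loglik()
    for _ in range(max_cycles):
        engine = TreeLikelihood(tree, aln, model)
        engine.optimize_branches(tol=tol, max_sweeps=branch_sweeps_per_cycle)
        model, new_ll = optimize_rate_params(tree, aln, model)
        if new_ll - ll < tol:
            ll = max(ll, new_ll)
            break
        ll = new_ll
    return tree, model, ll


def aic(loglik: float, n_params: int) -> float:
    return 2.0 * n_params - 2.0 * loglik


def select_model(
    aln: AminoAlignment,
    tree: PhyloTree,
    candidates: list[str],
    tol: float = 1e-3,
    max_cycles: int = 8,
) -> pd.DataFrame:
    """Fit each candidate model spec and rank by AIC (lowest first).

    Free parameters per candidate: branch lengths, plus 1 for +G, 1 for +I
    and 19 for +F. Returns a DataFrame with columns ``model``, ``loglik``,
    ``n_params``, ``aic``, ``alpha``, ``p_inv``, best model in row 0.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    n_branches = tree.n_edges()
    rows = []
    for spec in candidates:
        model = parse_model_spec(spec, alignment=aln)
        work = tree.copy()
        _, fitted, ll = fit_model(work, aln, model, tol=tol, max_cycles=max_cycles)
        n_params = n_branches + fitted.n_free_params()
        rows.append(
            {
                "model": spec,
                "loglik": ll,
                "n_params": n_params,
                "aic": aic(ll, n_params),
                "alpha": fitted.alpha,
                "p_inv": fitted.p_inv,
            }
        )
    table = pd.DataFrame(rows).sort_values(["aic", "model"], kind="mergesort")
    return table.reset_index(drop=True)
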