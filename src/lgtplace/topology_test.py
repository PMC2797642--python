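"""Per-topology site log-likelihoods, RELL bootstrap, and the
Shimodaira-Hasegawa test with a tabular report.

The SH procedure: observed differences to the best tree; RELL-resampled
totals per topology; per-topology centering; the null difference for each
replicate is (max centered value) - (own centered value); one-sided p-value
with a +1/(B+1) finite-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_core.alignment import AminoAlignment
from .phylo_core.likelihood import site_loglikelihoods
from .phylo_core.models import SubstModel
from .phylo_core.likelihood import optimize_branch_lengths
from .phylo_core.optimize import fit_model
from .phylo_core.tree import PhyloTree
from .topology_moves import TopologySet

REOPT_MODES = ("fixed", "branches", "full")


@dataclass
class SiteLoglikMatrix:
    """Topologies x sites matrix of per-site log-likelihoods."""

    ids: list[str]
    matrix: np.ndarray = field(repr=False)
    trees: list[PhyloTree] | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match topology ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite site log-likelihoods")

    @property
    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def nsites(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.T, columns=self.ids)


@dataclass
class SHRow:
    tree_id: str
    loglik: float
    d_lh: float
    sd: float
    p_value: float
    significantly_worse: bool


@dataclass
class SHReport:
    rows: list[SHRow]
    alpha: float
    n_replicates: int

    @property
    def best_index(self) -> int:
        for i, r in enumerate(self.rows):
            if r.d_lh == 0.0:
                return i
        raise ValueError("report has no best row")

    def row_for(self, tree_id: str) -> SHRow:
        for r in self.rows:
            if r.tree_id == tree_id:
                return r
        raise KeyError(tree_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Tree": [r.tree_id for r in self.rows],
                "Likelihood": [r.loglik for r in self.rows],
                "D_LH": [r.d_lh for r in self.rows],
                "SD": [r.sd for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
                "SignificantlyWorse": [
                    "Yes" if r.significantly_worse else "No" for r in self.rows
                ],
            }
        )


def per_topology_site_ll(
    topologies: TopologySet | list[PhyloTree],
    aln: AminoAlignment,
    model: SubstModel,
    reopt: str = "branches",
    ids: list[str] | None = None,
    tol: float = 1e-3,
    max_sweeps: int = 10,
) -> SiteLoglikMatrix:
    """Evaluate every topology (base tree first) against one alignment.

    ``reopt`` selects per-topology treatment: "fixed" scores trees as
    given, "branches" re-optimizes branch lengths (default), "full" also
    refits the rate parameters.
    """
    if reopt not in REOPT_MODES:
        raise ValueError(f"reopt must be one of {REOPT_MODES}")
    trees = topologies.trees if isinstance(topologies, TopologySet) else list(topologies)
    if ids is None:
        ids = ["Original tree"] + [f"Tree: {i}" for i in range(1, len(trees))]
    rows = []
    fitted_trees = []
    for tid, tree in zip(ids, trees):
        work = tree.copy()
        try:
            topo_model = model
            if reopt == "branches":
                optimize_branch_lengths(work, aln, topo_model, tol=tol, max_sweeps=max_sweeps)
            elif reopt == "full":
                _, topo_model, _ = fit_model(
                    work, aln, topo_model, tol=tol, max_cycles=max_sweeps
                )
            rows.append(site_loglikelihoods(work, aln, topo_model))
        except Exception as exc:
            raise RuntimeError(f"likelihood evaluation failed for {tid!r}") from exc
        fitted_trees.append(work)
    return SiteLoglikMatrix(ids=list(ids), matrix=np.vstack(rows), trees=fitted_trees)


def rell_bootstrap(
    matrix: SiteLoglikMatrix | np.ndarray, B: int = 1000, seed: int = 0
) -> np.ndarray:
    """Resampling-estimated log-likelihoods: B multinomial site-weight
    draws, returning a (B, n_topologies) array of reweighted totals."""
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    M = matrix.matrix if isinstance(matrix, SiteLoglikMatrix) else np.asarray(matrix)
    nsites = M.shape[1]
    rng = np.random.default_rng(seed)
    weights = rng.multinomial(nsites, np.full(nsites, 1.0 / nsites), size=B)
    return weights @ M.T


def sh_test(
    matrix: SiteLoglikMatrix,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SHReport:
    """Shimodaira-Hasegawa test of every topology against the best one.

    One-sided; conservative by construction (the centered-maximum null).
    ``D_LH`` is reported signed (non-positive, 0 for the best tree); ``SD``
    is the RELL standard deviation of the likelihood difference to the best
    tree; p-values carry the +1/(B+1) correction.
    """
    if B < 1:
        raise ValueError("need at least one RELL replicate")
    if len(matrix.ids) < 2:
        raise ValueError("need at least two topologies")
    totals = matrix.totals
    best = int(np.argmax(totals))
    D_obs = totals[best] - totals  # >= 0

    L = rell_bootstrap(matrix, B=B, seed=seed)  # (B, ntopo)
    R = L - L.mean(axis=0, keepdims=True)
    D_null = R.max(axis=1, keepdims=True) - R  # (B, ntopo)
    p = ((D_null >= D_obs[None, :]).sum(axis=0) + 1.0) / (B + 1.0)
    sd = (L[:, best][:, None] - L).std(axis=0, ddof=1)

    rows = [
        SHRow(
            tree_id=matrix.ids[a],
            loglik=float(totals[a]),
            d_lh=float(-D_obs[a]),
            sd=float(sd[a]),
            p_value=float(min(p[a], 1.0)),
            significantly_worse=bool(p[a] < alpha) and a != best,
        )
        for a in range(len(matrix.ids))
    ]
    return SHReport(rows=rows, alpha=alpha, n_replicates=B)


def write_report(report: SHReport, path, header_comment: str | None = None) -> None:
    """Write the report as TSV (best tree first, then input order), floats
    at 6 decimals, Yes/No rejection flags."""
    frame = report.to_frame()
    best = report.best_index
    order = [best] + [i for i in range(len(report.rows)) if i != best]
    frame = frame.iloc[order]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment)
        fh.write("\t".join(frame.columns) + "\n")
        for _, row in frame.iterrows():
            fh.write(
                f"{row.Tree}\t{row.Likelihood:.6f}\t{row.D_LH:.6f}\t"
                f"{row.SD:.6f}\t{row.p_value:.6f}\t{row.SignificantlyWorse}\n"
            )


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
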