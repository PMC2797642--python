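"""Substitution models: normalized reversible rate matrices, discrete-gamma
rate categories, invariant sites, and model-spec parsing ("WAG+G+I+F")."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

from .matrices import default_frequencies, exchangeabilities


class InvalidModelError(ValueError):
    pass


def build_rate_matrix(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """GTR-form rate matrix Q_ij = S_ij * pi_j, diagonal set for zero row
    sums, scaled to one expected substitution per unit time.

    Raises
    ------
    InvalidModelError
        If S is not symmetric/non-negative with a zero diagonal, or pi does
        not sum to 1 within 1e-9.
    """
    S = np.asarray(S, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if S.shape != (20, 20) or pi.shape != (20,):
        raise InvalidModelError("expected 20x20 S and length-20 pi")
    if not np.allclose(S, S.T, atol=1e-12):
        raise InvalidModelError("exchangeability matrix is not symmetric")
    if np.any(S < 0) or np.any(np.abs(np.diag(S)) > 1e-12):
        raise InvalidModelError("S must be non-negative with zero diagonal")
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise InvalidModelError("pi must be positive and sum to 1")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    return Q / mean_rate


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of the k equal-probability bins of Gamma(alpha, alpha),
    renormalized so the category mean is exactly 1."""
    if alpha <= 0:
        raise InvalidModelError("gamma shape must be positive")
    if k < 1:
        raise InvalidModelError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    # mean of Gamma(a,a) over [q_i, q_{i+1}] with mass 1/k each equals
    # k * (F_{a+1}(q_{i+1}) - F_{a+1}(q_i)) by the incomplete-gamma identity
    cuts = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    cdf_hi = gamma_dist.cdf(np.concatenate([cuts, [np.inf]]), alpha + 1, scale=1.0 / alpha)
    cdf_lo = gamma_dist.cdf(np.concatenate([[0.0], cuts]), alpha + 1, scale=1.0 / alpha)
    rates = k * (cdf_hi - cdf_lo)
    return rates / rates.mean()


@dataclass
class SubstModel:
    """Empirical amino-acid model with optional +G, +I, +F components.

    Attributes
    ----------
    name : str
        Base matrix name ("Poisson", "WAG", "LG").
    S : ndarray
        Symmetric exchangeabilities.
    pi : ndarray
        Stationary frequencies (model default or empirical).
    alpha : float or None
        Gamma shape; None means rate homogeneity.
    p_inv : float
        Proportion of invariant sites.
    k : int
        Number of discrete gamma categories.
    """

    name: str
    S: np.ndarray = field(repr=False)
    pi: np.ndarray = field(repr=False)
    alpha: float | None = None
    p_inv: float = 0.0
    k: int = 4
    empirical_freqs: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_inv < 1.0):
            raise InvalidModelError("p_inv must lie in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise InvalidModelError("alpha must be positive")
        self.S = np.asarray(self.S, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self._decompose()

    def _decompose(self) -> None:
        # symmetric similarity transform B = D^{1/2} Q D^{-1/2} has a real
        # spectrum for reversible Q; decompose once, reuse for every branch
        self.Q = build_rate_matrix(self.S, self.pi)
        sq = np.sqrt(self.pi)
        B = (self.Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        eigval, V = np.linalg.eigh(B)
        self._eigval = eigval
        self._right = V / sq[:, None]  # D^{-1/2} V
        self._left = (V * sq[:, None]).T  # V^T D^{1/2}

    # -- derived quantities ------------------------------------------------

    def rates(self) -> np.ndarray:
        """Variable-rate category rates (mean 1, equal weights); cached."""
        cached = getattr(self, "_rates_cache", None)
        if cached is not None:
            return cached
        if self.alpha is None:
            rates = np.ones(1)
        else:
            rates = discrete_gamma_rates(self.alpha, self.k)
        self._rates_cache = rates
        return rates

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), rows summing to 1."""
        P = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
        return np.clip(P, 0.0, None)

    def transition_matrices(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stack of P(t * r_c) for each rate category, shape (k, 20, 20)."""
        ex = np.exp(np.outer(rates, self._eigval) * t)  # (k, 20)
        P = np.einsum("ij,cj,jl->cil", self._right, ex, self._left)
        return np.clip(P, 0.0, None)

    def with_params(self, **kw) -> "SubstModel":
        """Copy with replaced parameters (recomputes the decomposition)."""
        m = replace(self, **kw)
        m.fit_pinv = getattr(self, "fit_pinv", False)
        return m

    def n_free_params(self) -> int:
        """Free model parameters: +G adds 1, +I adds 1, +F adds 19."""
        n = 0
        if self.alpha is not None:
            n += 1
        if self.p_inv > 0 or self._fit_pinv:
            n += 1
        if self.empirical_freqs:
            n += 19
        return n

    @property
    def _fit_pinv(self) -> bool:
        return getattr(self, "fit_pinv", False)

    def spec_string(self) -> str:
        s = self.name
        if self.alpha is not None:
            s += "+G"
        if self.p_inv > 0:
            s += "+I"
        if self.empirical_freqs:
            s += "+F"
        return s


def parse_model_spec(
    spec: str,
    alignment=None,
    alpha: float = 1.0,
    p_inv: float = 0.0,
    k: int = 4,
) -> SubstModel:
    """Build a SubstModel from a spec string such as "WAG+G+I+F" or
    "LG+G+F".

    "+F" requires an alignment to take empirical frequencies from. "+G"
    enables discrete-gamma rates initialized at ``alpha``; "+I" enables a
    (fittable) invariant-site proportion initialized at ``p_inv``.
    """
    parts = spec.replace(" ", "").split("+")
    base, flags = parts[0], {p.upper() for p in parts[1:]}
    bad = flags - {"G", "I", "F"}
    if bad:
        raise InvalidModelError(f"unknown model components {sorted(bad)} in {spec!r}")
    S = exchangeabilities(base)
    if "F" in flags:
        if alignment is None:
            raise InvalidModelError("'+F' model requires an alignment")
        pi = alignment.empirical_frequencies()
    else:
        pi = default_frequencies(base)
    model = SubstModel(
        name=base if base.upper() != "POISSON" else "Poisson",
        S=S,
        pi=pi,
        alpha=alpha if "G" in flags else None,
        p_inv=p_inv if "I" in flags else 0.0,
        k=k,
        empirical_freqs="F" in flags,
    )
    model.fit_pinv = "I" in flags
    return model
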