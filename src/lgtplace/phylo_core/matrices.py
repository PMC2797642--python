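"""Tabulated amino-acid exchangeability matrices (Poisson, WAG, LG)."""

from __future__ import annotations

import numpy as np

from ._matrix_data import LG_FREQS, LG_LOWER, WAG_FREQS, WAG_LOWER


def _expand(lower: list[list[float]]) -> np.ndarray:
    S = np.zeros((20, 20))
    for i, row in enumerate(lower, start=1):
        for j, v in enumerate(row):
            S[i, j] = S[j, i] = v
    return S


def exchangeabilities(name: str) -> np.ndarray:
    """Symmetric 20x20 exchangeability matrix with zero diagonal."""
    key = name.upper()
    if key == "POISSON":
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        return S
    if key == "WAG":
        return _expand(WAG_LOWER)
    if key == "LG":
        return _expand(LG_LOWER)
    raise ValueError(f"unknown exchangeability matrix {name!r}")


def default_frequencies(name: str) -> np.ndarray:
    """Model-default stationary frequencies (uniform for Poisson)."""
    key = name.upper()
    if key == "POISSON":
        return np.full(20, 0.05)
    if key == "WAG":
        pi = np.array(WAG_FREQS)
    elif key == "LG":
        pi = np.array(LG_FREQS)
    else:
        raise ValueError(f"unknown matrix {name!r}")
    return pi / pi.sum()


MATRIX_NAMES = ("Poisson", "WAG", "LG")
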