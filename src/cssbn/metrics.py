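"""Comparison metrics for transition matrices and state distributions.

Matrix norms on the difference ``D = A - B``: the 1-norm is the maximum
column sum of ``|D|``, the infinity norm the maximum row sum, and the
2-norm the largest singular value of ``D`` (the spectral norm).  Vector
norms are the usual l1 / l2 / l-infinity on the difference of
distributions.
"""

from __future__ import annotations

import numpy as np

from .exact import StateDistribution, TransitionMatrix

__all__ = ["NORM_KINDS", "matrix_norm_diff", "vector_norm_diff", "max_relative_error"]

NORM_KINDS = ("one", "two", "infinity")

_ALIASES = {
    "one": "one", "1": "one", 1: "one",
    "two": "two", "2": "two", 2: "two",
    "infinity": "infinity", "inf": "infinity", "max": "infinity", np.inf: "infinity",
}


def _normalize_kind(kind) -> str:
    try:
        return _ALIASES[kind if not isinstance(kind, str) else kind.lower()]
    except (KeyError, TypeError):
        raise ValueError(f"unknown norm kind {kind!r}; choose from {NORM_KINDS}") from None


def _entries(x, other) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, (TransitionMatrix, StateDistribution)) and isinstance(
        other, (TransitionMatrix, StateDistribution)
    ):
        x.ordering.require_same(other.ordering)
    a = np.asarray(x, dtype=float)
    b = np.asarray(other, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def matrix_norm_diff(a, b, kind="infinity") -> float:
    """Norm of the difference of two equally-ordered transition matrices."""
    x, y = _entries(a, b)
    if x.ndim != 2:
        raise ValueError("matrix_norm_diff expects matrices")
    d = x - y
    order = {"one": 1, "two": 2, "infinity": np.inf}[_normalize_kind(kind)]
    return float(np.linalg.norm(d, ord=order))


def vector_norm_diff(a, b, kind="infinity") -> float:
    """Norm of the difference of two equally-ordered distributions."""
    x, y = _entries(a, b)
    if x.ndim != 1:
        raise ValueError("vector_norm_diff expects distributions")
    d = x - y
    order = {"one": 1, "two": 2, "infinity": np.inf}[_normalize_kind(kind)]
    return float(np.linalg.norm(d, ord=order))


def max_relative_error(estimate, truth) -> float:
    """Largest state-wise relative error ``|est - true| / true``.

    Every entry of ``truth`` must be strictly positive (guaranteed for the
    steady state of an ergodic chain).
    """
    est, tru = _entries(estimate, truth)
    if (tru <= 0).any():
        raise ValueError("truth distribution has non-positive entries")
    return float(np.max(np.abs(est - tru) / tru))
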