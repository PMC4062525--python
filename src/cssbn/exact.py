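"""Exact Markov-chain analysis of a context-sensitive PBN.

The joint chain lives on ``(context, GAP)`` states.  One step applies the
source context's (perturbed) Boolean map to the GAP and then switches the
context: with probability ``1 - q`` the context is kept, with probability
``q`` a context is redrawn from the selection probabilities ``{C_r}`` (the
current context may be redrawn).  The transition probability from ``(s, y)``
to ``(r, x)`` is therefore

    P[(s, y) -> (r, x)] = Ptilde_s[y, x] * ((1 - q) * [r == s] + q * C_r)

where ``Ptilde_s`` is the single-context matrix with perturbation: a gene
flips independently with probability ``p``, and if any gene flips the flip
pattern overrides the Boolean update, so

    Ptilde_s[y, x] = (1-p)**n * [f_s(y) = x] + p**h (1-p)**(n-h) * [h >= 1]

with ``h`` the Hamming distance between the GAPs ``y`` and ``x``.  For
``p > 0`` the joint chain is ergodic and has a unique stationary
distribution, found here by power iteration.

Matrices are row-stochastic with rows as source states; joint states are
ordered context-major (``(s - 1) * 2**n + d``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import Context, JointState, PBNModel, enumerate_contexts

__all__ = [
    "Ordering",
    "TransitionMatrix",
    "StateDistribution",
    "SSDOptions",
    "SteadyStateResult",
    "SizeCapError",
    "OrderingError",
    "bn_transition_matrix",
    "perturbed_transition_matrix",
    "transition_probability",
    "joint_transition_matrix",
    "instantaneous_stm",
    "steady_state",
    "marginal_gap_distribution",
]

logger = logging.getLogger(__name__)

#: refuse to materialize matrices with more entries than this by default
DEFAULT_MAX_ENTRIES = 1 << 22


class SizeCapError(MemoryError):
    """An exact matrix would exceed the configured size cap.

    For networks past this size use the bit-stream simulation engine
    (:mod:`cssbn.circuit`), which never materializes the joint matrix.
    """


class OrderingError(ValueError):
    """Two objects with incompatible state orderings were combined."""


@dataclass(frozen=True)
class Ordering:
    """State labeling of a matrix or distribution.

    ``k == 1`` denotes GAP-only ordering (size ``2**n``); ``k > 1`` denotes
    joint ordering over ``(context, GAP)`` states, context-major, GAP-major
    within each context block (size ``2**n * k``).
    """

    n: int
    k: int = 1

    @property
    def size(self) -> int:
        return (1 << self.n) * self.k

    @property
    def is_joint(self) -> bool:
        return self.k > 1

    def labels(self) -> list[str]:
        """Human-readable state labels: ``d`` for GAPs, ``(ctx, d)`` joint."""
        if self.k == 1:
            return [str(d) for d in range(1, (1 << self.n) + 1)]
        return [
            f"({s},{d})"
            for s in range(1, self.k + 1)
            for d in range(1, (1 << self.n) + 1)
        ]

    def require_same(self, other: "Ordering") -> None:
        if self != other:
            raise OrderingError(f"ordering mismatch: {self} vs {other}")


@dataclass
class TransitionMatrix:
    """Row-stochastic one-step transition matrix with its state ordering."""

    entries: np.ndarray
    ordering: Ordering

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        m = self.ordering.size
        if self.entries.shape != (m, m):
            raise ValueError(
                f"matrix shape {self.entries.shape} does not match ordering size {m}"
            )

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.entries, dtype=dtype)

    def validate(self, tol: float = 1e-9) -> None:
        if (self.entries < -tol).any():
            raise ValueError("negative transition probability")
        rows = self.entries.sum(axis=1)
        bad = np.abs(rows - 1.0) > tol
        if bad.any():
            raise ValueError(f"{bad.sum()} rows do not sum to 1 (max dev {np.abs(rows - 1).max():.3g})")


@dataclass
class StateDistribution:
    """Probability distribution over GAP or joint states."""

    probs: np.ndarray
    ordering: Ordering

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.ordering.size,):
            raise ValueError(
                f"distribution length {self.probs.shape} does not match "
                f"ordering size {self.ordering.size}"
            )

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.probs, dtype=dtype)

    @classmethod
    def uniform(cls, ordering: Ordering) -> "StateDistribution":
        m = ordering.size
        return cls(np.full(m, 1.0 / m), ordering)

    def validate(self, tol: float = 1e-9) -> None:
        if (self.probs < -tol).any():
            raise ValueError("negative probability")
        if abs(self.probs.sum() - 1.0) > tol:
            raise ValueError(f"distribution sums to {self.probs.sum()!r}")


@dataclass(frozen=True)
class SSDOptions:
    """Convergence control for steady-state computations.

    ``epsilon`` is the infinity-norm threshold on the difference between
    consecutive iterates; iteration stops when the residual drops below it
    or after ``max_iterations`` steps.  ``initial`` is a
    :class:`StateDistribution` or the string ``"uniform"``.
    """

    epsilon: float = 1e-8
    max_iterations: int = 10_000
    initial: StateDistribution | str = "uniform"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class SteadyStateResult:
    """Stationary distribution plus convergence diagnostics."""

    distribution: StateDistribution
    iterations: int
    residual: float
    converged: bool


# ---------------------------------------------------------------------------
# Single-context matrices

def bn_transition_matrix(model: PBNModel, context: Context) -> TransitionMatrix:
    """Deterministic 0/1 GAP transition matrix of one context (no perturbation)."""
    n = model.n
    m = 1 << n
    nxt = context.next_gap_table(model)
    entries = np.zeros((m, m))
    entries[np.arange(m), nxt] = 1.0
    return TransitionMatrix(entries, Ordering(n))


def _hamming_matrix(n: int) -> np.ndarray:
    g = np.arange(1 << n)
    x = g[:, None] ^ g[None, :]
    h = np.zeros_like(x)
    for j in range(n):
        h += (x >> j) & 1
    return h


def perturbed_transition_matrix(
    model: PBNModel,
    context: Context,
    p: float | None = None,
    max_entries: int = DEFAULT_MAX_ENTRIES,
) -> TransitionMatrix:
    """GAP transition matrix of one context under per-gene perturbation.

    With probability ``(1-p)**n`` no gene flips and the context's Boolean
    map is applied; otherwise the realized flip pattern (Hamming weight
    ``h >= 1``) replaces the update.
    """
    if p is None:
        p = model.perturbation_rate
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"perturbation rate {p} not in [0, 1]")
    n = model.n
    m = 1 << n
    if m * m > max_entries:
        raise SizeCapError(
            f"{m}x{m} GAP matrix exceeds cap of {max_entries} entries"
        )
    h = _hamming_matrix(n)
    with np.errstate(divide="ignore"):
        entries = np.where(h > 0, p**h * (1.0 - p) ** (n - h), 0.0)
    nxt = context.next_gap_table(model)
    entries[np.arange(m), nxt] += (1.0 - p) ** n
    return TransitionMatrix(entries, Ordering(n))


# ---------------------------------------------------------------------------
# Joint chain

def _context_probs(model: PBNModel) -> np.ndarray:
    return np.array([c.probability for c in enumerate_contexts(model)])


def transition_probability(
    a: JointState | tuple[int, int],
    b: JointState | tuple[int, int],
    model: PBNModel,
    p: float | None = None,
    q: float | None = None,
) -> float:
    """Exact one-step probability from joint state ``a = (s, y)`` to ``b = (r, x)``.

    States use 1-based context numbers and GAP indices ``d``.
    """
    a, b = JointState(*a), JointState(*b)
    if q is None:
        q = model.switching_probability
    contexts = enumerate_contexts(model)
    k, m = len(contexts), model.n_states
    for st in (a, b):
        if not (1 <= st.context <= k and 1 <= st.gap <= m):
            raise ValueError(f"joint state {st} out of range (k={k}, 2^n={m})")
    ptilde = perturbed_transition_matrix(model, contexts[a.context - 1], p=p)
    f_term = ptilde.entries[a.gap - 1, b.gap - 1]
    c_r = contexts[b.context - 1].probability
    switch = q * c_r + ((1.0 - q) if b.context == a.context else 0.0)
    return float(f_term * switch)


def joint_transition_matrix(
    model: PBNModel,
    p: float | None = None,
    q: float | None = None,
    intervention_map: np.ndarray | None = None,
    max_entries: int = DEFAULT_MAX_ENTRIES,
) -> TransitionMatrix:
    """The ``(2**n * k) x (2**n * k)`` joint STM of the CSPBN.

    Block row ``s``, block column ``r`` equals
    ``Ptilde_s * ((1 - q) [r == s] + q C_r)``: the Boolean/perturbation map
    of the source context applied first, then the context switch.

    ``intervention_map``, if given, is a length-``2**n`` array mapping each
    post-transition GAP (0-based) to its GAP after the control action; it is
    composed onto every context's perturbed matrix.

    Raises :class:`SizeCapError` above ``max_entries`` matrix entries —
    larger networks are the bit-stream engine's territory.
    """
    if q is None:
        q = model.switching_probability
    if model.topology_incomplete:
        logger.warning(
            "joint STM of a topology-incomplete scaffold: placeholder truth "
            "tables, dynamics are not biologically meaningful"
        )
    contexts = enumerate_contexts(model)
    k, m = len(contexts), model.n_states
    size = k * m
    if size * size > max_entries:
        raise SizeCapError(
            f"joint STM would be {size}x{size} ({size * size} entries), above the "
            f"cap of {max_entries}; use the stochastic simulation engine instead"
        )
    c = np.array([ctx.probability for ctx in contexts])
    entries = np.zeros((size, size))
    for s, ctx in enumerate(contexts):
        ptilde = perturbed_transition_matrix(model, ctx, p=p).entries
        if intervention_map is not None:
            post = np.zeros((m, m))
            np.add.at(post.T, np.asarray(intervention_map), ptilde.T)
            ptilde = post
        rows = slice(s * m, (s + 1) * m)
        for r in range(k):
            w = q * c[r] + (1.0 - q if r == s else 0.0)
            if w:
                entries[rows, r * m : (r + 1) * m] = w * ptilde
    return TransitionMatrix(entries, Ordering(model.n, k))


def instantaneous_stm(
    model: PBNModel, p: float | None = None
) -> TransitionMatrix:
    """GAP-level STM of the instantaneous PBN (``q = 1``): ``sum_j C_j Ptilde_j``."""
    contexts = enumerate_contexts(model)
    m = model.n_states
    entries = np.zeros((m, m))
    for ctx in contexts:
        entries += ctx.probability * perturbed_transition_matrix(model, ctx, p=p).entries
    return TransitionMatrix(entries, Ordering(model.n))


# ---------------------------------------------------------------------------
# Steady state

def steady_state(
    matrix: TransitionMatrix, options: SSDOptions | None = None
) -> SteadyStateResult:
    """Stationary distribution by power iteration ``x <- x A``.

    Iterates until ``||x^(m+1) - x^(m)||_inf < epsilon`` or the iteration
    cap; non-convergence is reported through the result's ``converged``
    flag and a warning carrying the final residual.  For an ergodic chain
    (any ``p > 0``) the result is independent of the initial distribution.
    """
    if options is None:
        options = SSDOptions()
    a = matrix.entries
    if isinstance(options.initial, StateDistribution):
        options.initial.ordering.require_same(matrix.ordering)
        x = options.initial.probs.astype(float).copy()
    else:
        x = np.full(a.shape[0], 1.0 / a.shape[0])
    residual = np.inf
    for it in range(1, options.max_iterations + 1):
        x_next = x @ a
        residual = float(np.abs(x_next - x).max())
        x = x_next
        if residual < options.epsilon:
            x = x / x.sum()  # shed accumulated round-off
            return SteadyStateResult(
                StateDistribution(x, matrix.ordering), it, residual, True
            )
    warnings.warn(
        f"power iteration did not converge in {options.max_iterations} steps "
        f"(final residual {residual:.3g})",
        stacklevel=2,
    )
    return SteadyStateResult(
        StateDistribution(x / x.sum(), matrix.ordering),
        options.max_iterations,
        residual,
        False,
    )


def marginal_gap_distribution(joint: StateDistribution) -> StateDistribution:
    """Collapse a joint (context, GAP) distribution onto GAPs.

    The probability of each GAP is the sum of its probabilities over all
    contexts.  A single-context (``k = 1``) distribution is already
    GAP-marginal and passes through unchanged.
    """
    n, k = joint.ordering.n, joint.ordering.k
    if k == 1:
        return StateDistribution(joint.probs.copy(), Ordering(n))
    gaps = joint.probs.reshape(k, 1 << n).sum(axis=0)
    return StateDistribution(gaps, Ordering(n))
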