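"""Bit-stream simulation of a context-sensitive PBN.

One bit position of every stochastic sequence is treated as one independent
Monte-Carlo *lane* carrying a full joint sample (context label + GAP), so
within-lane gene-to-gene correlation is preserved by construction.  A
single step of the circuit realizes the exact one-step law of the chain:

1. each lane's context functions are applied to its GAP;
2. per-gene perturbation bits are drawn with probability ``p``; if any is
   set, the flip pattern overrides the function output (XOR bank + wide OR
   + bus multiplexer);
3. a switch bit with probability ``q`` decides whether the lane redraws its
   context from the selection probabilities ``{C_j}`` (2-to-1 multiplexers
   with control sequence ``Q``);
4. an optional intervention stage flips the control gene on undesirable
   GAPs.

Probability-encoding control sequences (``Q``, the context-selection
bundle, the perturbation sequences) use fixed-count random permutations by
default (``sequence_mode="permutation"``), which removes their count
variance; ``"bernoulli"`` gives the classical independent-draw encoding.
Control sequences are redrawn at every frame.

Transition matrices are estimated row by row (all lanes started in one
joint state, one step, empirical next-state frequencies), and stationary
distributions either by time-frame expansion — iterating the circuit until
consecutive empirical distributions agree within ``epsilon`` in the
infinity norm — or by solving the estimated matrix with the exact engine's
power iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exact import (
    Ordering,
    SizeCapError,
    SSDOptions,
    StateDistribution,
    SteadyStateResult,
    TransitionMatrix,
    steady_state,
)
from .intervention import InterventionSpec, intervention_gap_map
from .model import PBNModel, enumerate_contexts
from .stochastic import (
    RandomSource,
    bernoulli_sequence,
    categorical_labels,
    exact_counts,
    permutation_sequence,
    stratified_counts,
)

__all__ = [
    "LaneEnsemble",
    "CSSBNCircuit",
    "TimeFrameResult",
    "build_cssbn",
]

logger = logging.getLogger(__name__)

#: default cap on estimated joint STM rows x columns
DEFAULT_MAX_ENTRIES = 1 << 26

#: defaults for empirical (time-frame) convergence; the exact engine's
#: 1e-8 threshold is unreachable through Monte-Carlo noise of order L^-1/2
TIME_FRAME_OPTIONS = SSDOptions(epsilon=1e-3, max_iterations=500)


@dataclass
class LaneEnsemble:
    """Joint sample per lane at one time frame.

    ``contexts`` holds 0-based context labels, ``gaps`` 0-based GAP
    integers; both have one entry per lane.
    """

    contexts: np.ndarray
    gaps: np.ndarray

    def __post_init__(self) -> None:
        self.contexts = np.asarray(self.contexts, dtype=np.int64)
        self.gaps = np.asarray(self.gaps, dtype=np.int64)
        if self.contexts.shape != self.gaps.shape:
            raise ValueError("context and GAP lane counts differ")

    @property
    def n_lanes(self) -> int:
        return self.contexts.size

    def joint_indices(self, n: int) -> np.ndarray:
        """Joint state index per lane, context-major ordering."""
        return self.contexts * (1 << n) + self.gaps

    def empirical_distribution(self, ordering: Ordering) -> StateDistribution:
        """Exactly normalized empirical joint distribution (counts / L)."""
        counts = np.bincount(self.joint_indices(ordering.n), minlength=ordering.size)
        return StateDistribution(counts / self.n_lanes, ordering)


@dataclass
class TimeFrameResult:
    """Empirical stationary distribution plus convergence diagnostics."""

    distribution: StateDistribution
    frames: int
    residual: float
    converged: bool


class CSSBNCircuit:
    """One-step stochastic circuit for a PBN with context switching.

    Built with :func:`build_cssbn`.  ``q = 1`` degenerates to an
    instantaneous stochastic Boolean network (fresh context every step);
    ``q = 0`` freezes each lane's context, i.e. a fixed Boolean network
    per lane.
    """

    def __init__(
        self,
        model: PBNModel,
        length: int,
        source: RandomSource,
        sequence_mode: str = "permutation",
        intervention: InterventionSpec | None = None,
    ):
        if length < 1:
            raise ValueError("sequence length L must be >= 1")
        if sequence_mode not in ("permutation", "bernoulli"):
            raise ValueError(f"unknown sequence mode {sequence_mode!r}")
        if model.topology_incomplete:
            logger.warning(
                "simulating a topology-incomplete scaffold: placeholder truth "
                "tables, dynamics are not biologically meaningful"
            )
        self.model = model
        self.length = int(length)
        self.source = source
        self.sequence_mode = sequence_mode
        self.intervention = intervention

        contexts = enumerate_contexts(model)
        self.k = len(contexts)
        self.n = model.n
        self.context_probs = np.array([c.probability for c in contexts])
        # (k, 2**n) deterministic next-GAP lookup, one row per context
        self.next_table = np.stack([c.next_gap_table(model) for c in contexts])
        self.intervention_map = (
            intervention_gap_map(intervention, self.n)
            if intervention is not None
            else None
        )
        self.ordering = Ordering(self.n, self.k)
        self._rng_gamma = source.stream("perturbation")
        self._rng_switch = source.stream("context-switch")
        self._rng_select = source.stream("context-select")
        self._rng_init = source.stream("initial-state")
        self._rng_row = source.stream("stm-rows")

    # -- sequence generation -------------------------------------------------

    def _bits(self, prob: float, rng: np.random.Generator) -> np.ndarray:
        if self.sequence_mode == "permutation":
            return permutation_sequence(prob, self.length, rng)
        return bernoulli_sequence(prob, self.length, rng)

    def _perturbation_vectors(self) -> np.ndarray:
        """Per-lane flip pattern as packed GAP integers (gene 1 = MSB)."""
        p = self.model.perturbation_rate
        gamma = np.zeros(self.length, dtype=np.int64)
        if p == 0.0:
            return gamma
        for i in range(self.n):
            gamma |= self._bits(p, self._rng_gamma).astype(np.int64) << (self.n - 1 - i)
        return gamma

    # -- dynamics ------------------------------------------------------------

    def initial_ensemble(
        self, initial: StateDistribution | str = "uniform"
    ) -> LaneEnsemble:
        """Lanes initialized with exact (largest-remainder) counts per joint state."""
        if isinstance(initial, StateDistribution):
            initial.ordering.require_same(self.ordering)
            probs = initial.probs
        else:
            probs = np.full(self.ordering.size, 1.0 / self.ordering.size)
        counts = exact_counts(probs, self.length)
        joint = np.repeat(np.arange(self.ordering.size), counts)
        self._rng_init.shuffle(joint)
        return LaneEnsemble(joint // (1 << self.n), joint & ((1 << self.n) - 1))

    def step(self, state: LaneEnsemble) -> LaneEnsemble:
        """Advance every lane one time frame."""
        if state.n_lanes != self.length:
            raise ValueError(f"expected {self.length} lanes, got {state.n_lanes}")
        # 1. predictor evaluation in each lane's context
        fx = self.next_table[state.contexts, state.gaps]
        # 2. perturbation override: any flipped gene replaces the update
        gamma = self._perturbation_vectors()
        perturbed = gamma != 0
        next_gaps = np.where(perturbed, state.gaps ^ gamma, fx)
        # 3. context switch with probability q, new context drawn from {C_j}
        q = self.model.switching_probability
        next_contexts = state.contexts.copy()
        if q > 0.0:
            switch = self._bits(q, self._rng_switch).astype(bool)
            n_switch = int(switch.sum())
            if n_switch:
                next_contexts[switch] = categorical_labels(
                    self.context_probs, n_switch, self._rng_select, self.sequence_mode
                )
        # 4. optional intervention on the post-transition GAP
        if self.intervention_map is not None:
            next_gaps = self.intervention_map[next_gaps]
        return LaneEnsemble(next_contexts, next_gaps)

    # -- estimation ----------------------------------------------------------

    def _row_counts_stratified(self, s: int, g: int) -> np.ndarray:
        """Next-state lane counts for all lanes started at ``(s, g)``, with the
        control tuple realized jointly at fixed counts.

        Because every lane of an STM row shares one input state, the joint
        law of its control signals — perturbation pattern crossed with the
        keep/switch outcome — is a known product distribution; realizing it
        with stratified counts (every cell within one lane of ``prob * L``)
        is the fixed-count non-Bernoulli encoding applied to the whole
        control bundle rather than to each sequence separately, and removes
        the cross-association noise between bundles.
        """
        m = 1 << self.n
        p = self.model.perturbation_rate
        q = self.model.switching_probability
        # perturbation-pattern law over 2**n flip vectors
        weights = np.ones(m)
        for i in range(self.n):
            bit = (np.arange(m) >> (self.n - 1 - i)) & 1
            weights *= np.where(bit, p, 1.0 - p)
        # switch outcome: column 0 keeps the context, column 1+r selects r
        switch = np.concatenate(([1.0 - q], q * self.context_probs))
        cells = stratified_counts(
            np.outer(weights, switch).ravel(), self.length, self._rng_row
        ).reshape(m, self.k + 1)
        # destination GAP per pattern: function output if no flip, else XOR
        dest_gap = np.arange(m) ^ g
        dest_gap[0] = self.next_table[s, g]
        if self.intervention_map is not None:
            dest_gap = self.intervention_map[dest_gap]
        dest_ctx = np.concatenate(([s], np.arange(self.k)))
        counts = np.zeros(self.ordering.size, dtype=np.int64)
        np.add.at(counts, (dest_ctx[None, :] * m + dest_gap[:, None]).ravel(), cells.ravel())
        return counts

    def estimate_stm(
        self, max_entries: int = DEFAULT_MAX_ENTRIES
    ) -> TransitionMatrix:
        """Empirical joint STM, one simulated step per input state.

        Every row starts all ``L`` lanes in that joint state, advances one
        frame and records next-state frequencies; rows are integer counts
        over ``L`` and sum to 1.  In permutation mode the row's control
        sequences are realized jointly at fixed counts (see
        :meth:`_row_counts_stratified`); Bernoulli mode steps the lane
        ensemble with independent draws.
        """
        size = self.ordering.size
        if size * size > max_entries:
            raise SizeCapError(
                f"estimated joint STM would be {size}x{size}; above the cap of "
                f"{max_entries} entries use time-frame expansion instead"
            )
        m = 1 << self.n
        entries = np.empty((size, size))
        lanes = self.length
        for s in range(self.k):
            for g in range(m):
                if self.sequence_mode == "permutation":
                    counts = self._row_counts_stratified(s, g)
                else:
                    state = LaneEnsemble(
                        np.full(lanes, s, dtype=np.int64),
                        np.full(lanes, g, dtype=np.int64),
                    )
                    nxt = self.step(state)
                    counts = np.bincount(nxt.joint_indices(self.n), minlength=size)
                entries[s * m + g] = counts / lanes
        return TransitionMatrix(entries, self.ordering)

    def estimate_ssd_time_frame(
        self, options: SSDOptions | None = None
    ) -> TimeFrameResult:
        """Stationary distribution by time-frame expansion.

        Iterates the circuit from the initial distribution until the
        infinity norm between consecutive empirical joint distributions
        drops below ``epsilon`` (default 1e-3, a scale the Monte-Carlo
        noise floor ~``L**-0.5`` can actually reach) or the frame cap.
        """
        if options is None:
            options = TIME_FRAME_OPTIONS
        state = self.initial_ensemble(options.initial)
        dist = state.empirical_distribution(self.ordering).probs
        residual = np.inf
        for frame in range(1, options.max_iterations + 1):
            state = self.step(state)
            new = state.empirical_distribution(self.ordering).probs
            residual = float(np.abs(new - dist).max())
            dist = new
            if residual < options.epsilon:
                logger.info(
                    "time-frame expansion converged: %d frames, residual %.3g",
                    frame,
                    residual,
                )
                return TimeFrameResult(
                    StateDistribution(dist, self.ordering), frame, residual, True
                )
        logger.warning(
            "time-frame expansion hit the %d-frame cap (residual %.3g)",
            options.max_iterations,
            residual,
        )
        return TimeFrameResult(
            StateDistribution(dist, self.ordering),
            options.max_iterations,
            residual,
            False,
        )

    def ssd_from_estimated_stm(
        self, options: SSDOptions | None = None
    ) -> SteadyStateResult:
        """Estimate the joint STM, then solve it with exact power iteration.

        This matrix-then-solve pathway is the engine's most accurate route
        to the stationary distribution at a given sequence length.
        """
        return steady_state(self.estimate_stm(), options)


def build_cssbn(
    model: PBNModel,
    length: int = 10_000,
    source: RandomSource | int = 0,
    sequence_mode: str = "permutation",
    intervention: InterventionSpec | None = None,
) -> CSSBNCircuit:
    """Construct the stochastic circuit for ``model``.

    ``length`` is the stochastic sequence length ``L`` (number of
    Monte-Carlo lanes); accuracy improves as ``L**-0.5``.  ``source`` may
    be a :class:`RandomSource` or a bare integer seed.
    """
    if isinstance(source, int):
        source = RandomSource(source)
    return CSSBNCircuit(model, length, source, sequence_mode, intervention)
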