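"""Stochastic-logic primitives: probability-encoding bit sequences and gates.

Stochastic computation encodes a probability as the fraction of 1s in a
binary bit stream of length ``L``; ordinary logic gates then perform
probabilistic arithmetic (an AND multiplies independent probabilities, a
NOT complements, a multiplexer forms a weighted sum).  Two encodings are
provided:

* *Bernoulli* sequences: independent draws, binomial count variance.
* *non-Bernoulli* (permutation) sequences: a random permutation of a fixed
  count of 1s, ``round(prob * L)`` of them, so the encoded probability has
  zero count variance.  These make downstream estimates markedly more
  accurate at the same length.

Bit sequences are plain ``numpy`` ``uint8`` arrays of 0s and 1s.  All
randomness flows through named substreams of a single :class:`RandomSource`
so every experiment is reproducible from one integer seed.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RandomSource",
    "permutation_sequence",
    "bernoulli_sequence",
    "gate",
    "mux",
    "mux_bus",
    "mux_bank",
    "estimate_probability",
    "exact_counts",
    "categorical_labels",
    "select_lines_for_labels",
]

GATES = ("NOT", "AND", "OR", "XOR", "BUFFER")


class RandomSource:
    """Seeded factory of independent, named random substreams.

    ``stream(name)`` returns a fresh ``numpy`` generator whose state is a
    pure function of ``(seed, name)``: the same source constructed with the
    same seed yields bit-identical sequences for the same signal name.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)

    def stream(self, name: str) -> np.random.Generator:
        digest = hashlib.sha256(name.encode()).digest()
        words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
        return np.random.default_rng(np.random.SeedSequence([self.seed, *words]))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RandomSource(seed={self.seed})"


def _ones_count(prob: float, length: int) -> int:
    # round-half-to-even keeps the encoding unbiased over probability grids
    return int(np.rint(prob * length))


def permutation_sequence(
    prob: float, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Non-Bernoulli sequence: exactly ``round(prob * L)`` ones, randomly permuted."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"probability {prob} not in [0, 1]")
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    ones = _ones_count(prob, length)
    seq = np.zeros(length, dtype=np.uint8)
    seq[:ones] = 1
    rng.shuffle(seq)
    return seq


def bernoulli_sequence(
    prob: float, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli(prob) draws."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"probability {prob} not in [0, 1]")
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    return (rng.random(length) < prob).astype(np.uint8)


def _check_lengths(seqs: Sequence[np.ndarray]) -> None:
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"sequence length mismatch: {sorted(lengths)}")


def gate(kind: str, *operands: np.ndarray) -> np.ndarray:
    """Bitwise logic gate over equal-length sequences.

    ``NOT`` and ``BUFFER`` take one operand; ``AND``/``OR``/``XOR`` take two
    or more and fold left.
    """
    kind = kind.upper()
    if kind not in GATES:
        raise ValueError(f"unknown gate {kind!r}; choose from {GATES}")
    if kind in ("NOT", "BUFFER"):
        if len(operands) != 1:
            raise ValueError(f"{kind} takes exactly one operand")
        x = np.asarray(operands[0], dtype=np.uint8)
        return (1 - x).astype(np.uint8) if kind == "NOT" else x.copy()
    if len(operands) < 2:
        raise ValueError(f"{kind} takes at least two operands")
    _check_lengths(operands)
    out = np.asarray(operands[0], dtype=np.uint8)
    for op in operands[1:]:
        op = np.asarray(op, dtype=np.uint8)
        if kind == "AND":
            out = out & op
        elif kind == "OR":
            out = out | op
        else:
            out = out ^ op
    return out.astype(np.uint8)


def mux(select: np.ndarray, in0: np.ndarray, in1: np.ndarray) -> np.ndarray:
    """2-to-1 multiplexer: output bit is ``in1`` where ``select`` is 1, else ``in0``.

    With independent inputs the output encodes ``(1 - s) a + s b``.
    """
    _check_lengths([select, in0, in1])
    return np.where(np.asarray(select, dtype=bool), in1, in0).astype(np.uint8)


def mux_bus(
    select: np.ndarray,
    lanes0: Sequence[np.ndarray],
    lanes1: Sequence[np.ndarray],
) -> list[np.ndarray]:
    """Bus multiplexer: one select sequence switches multi-bit lanes in lockstep."""
    if len(lanes0) != len(lanes1):
        raise ValueError("bus widths differ")
    return [mux(select, a, b) for a, b in zip(lanes0, lanes1)]


def mux_bank(select_lines: Sequence[np.ndarray], inputs: Sequence[np.ndarray]) -> np.ndarray:
    """Wide multiplexer driven by ``m`` binary-coded select lines.

    ``select_lines[0]`` is the most significant line; ``inputs`` must have
    ``2**m`` sequences.  Position ``t`` of the output copies position ``t``
    of ``inputs[code_t]``.
    """
    m = len(select_lines)
    if len(inputs) != 1 << m:
        raise ValueError(f"{len(inputs)} inputs for {m} select lines (need {1 << m})")
    _check_lengths(list(select_lines) + list(inputs))
    code = np.zeros(len(select_lines[0]), dtype=np.int64)
    for line in select_lines:
        code = (code << 1) | np.asarray(line, dtype=np.int64)
    stacked = np.stack([np.asarray(x, dtype=np.uint8) for x in inputs])
    return stacked[code, np.arange(stacked.shape[1])]


def estimate_probability(seq: np.ndarray) -> float:
    """Probability encoded by a sequence: its fraction of 1s."""
    seq = np.asarray(seq)
    if seq.size == 0:
        raise ValueError("empty sequence")
    return float(np.count_nonzero(seq)) / seq.size


# ---------------------------------------------------------------------------
# Categorical (context-selection) encoding

def exact_counts(probs: np.ndarray, length: int) -> np.ndarray:
    """Integer counts summing to ``length`` proportional to ``probs``.

    Largest-remainder rounding: the deterministic fixed-count analogue of
    the permutation encoding for a categorical distribution.  Ties in the
    fractional parts are broken by category order.
    """
    probs = np.asarray(probs, dtype=float)
    if length < 0:
        raise ValueError("length must be >= 0")
    target = probs * length
    base = np.floor(target).astype(np.int64)
    short = length - int(base.sum())
    if short:
        remainder = target - base
        top = np.argsort(-remainder, kind="stable")[:short]
        base[top] += 1
    return base


def stratified_counts(
    probs: np.ndarray, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Unbiased fixed-count realization of a categorical distribution.

    Each category receives ``floor(prob * L)`` lanes, and the remaining
    lanes are allocated without replacement with probability proportional
    to the fractional parts.  The counts always sum to ``length``, every
    count is within 1 of ``prob * L``, and the expectation equals
    ``prob * L`` exactly.
    """
    probs = np.asarray(probs, dtype=float)
    target = probs * length
    base = np.floor(target).astype(np.int64)
    short = length - int(base.sum())
    if short:
        remainder = target - base
        total = remainder.sum()
        extra = rng.choice(probs.size, size=short, replace=False, p=remainder / total)
        base[extra] += 1
    return base


def categorical_labels(
    probs: np.ndarray,
    length: int,
    rng: np.random.Generator,
    mode: str = "permutation",
) -> np.ndarray:
    """Length-``L`` stream of category labels encoding a categorical distribution.

    ``mode="permutation"`` realizes exact largest-remainder counts per
    category, randomly permuted (zero count variance); ``mode="bernoulli"``
    draws labels independently.
    """
    probs = np.asarray(probs, dtype=float)
    if mode == "permutation":
        counts = exact_counts(probs, length)
        labels = np.repeat(np.arange(len(probs)), counts)
        rng.shuffle(labels)
        return labels
    if mode == "bernoulli":
        return rng.choice(len(probs), size=length, p=probs / probs.sum())
    raise ValueError(f"unknown sequence mode {mode!r}")


def select_lines_for_labels(labels: np.ndarray, n_lines: int) -> list[np.ndarray]:
    """Binary-coded select-line sequences realizing a stream of category labels.

    Line 0 is the most significant bit of each label; feeding the lines to
    :func:`mux_bank` reproduces the labelled selection exactly, so the
    joint code distribution matches the label distribution by construction.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and labels.max() >= 1 << n_lines:
        raise ValueError(f"labels up to {labels.max()} need more than {n_lines} lines")
    return [
        ((labels >> (n_lines - 1 - i)) & 1).astype(np.uint8) for i in range(n_lines)
    ]
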