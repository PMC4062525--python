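"""Data model for probabilistic Boolean networks (PBNs) with context switching.

A PBN over ``n`` binary genes assigns each gene a set of Boolean predictor
functions, one of which is active at any time; a *context* is one fixed
choice of predictor per gene, i.e. a realized Boolean network.  A
context-sensitive PBN (CSPBN) holds its context until a random switch
(probability ``q`` per step) and flips individual gene states by random
perturbation (probability ``p`` per gene per step).

State conventions
-----------------
A gene activity profile (GAP) is the binary vector of all gene states.
Gene 1 is the most significant bit, and the decimal index of a GAP is

    d = sum_j 2**(n - j) * x_j + 1,      d in 1..2**n.

Internally GAPs are 0-based integers ``g = d - 1``; every user-facing
report uses the 1-based ``d``.  Contexts are enumerated lexicographically
in the per-gene predictor indices and numbered from 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import yaml

__all__ = [
    "NetworkValidationError",
    "PredictorFunction",
    "PBNModel",
    "Context",
    "JointState",
    "gap_index",
    "gap_bits",
    "enumerate_contexts",
    "top_context_mass",
    "parse_network",
    "load_network",
    "network_to_document",
    "save_network",
    "build_p53_network",
    "build_glioma_scaffold",
    "generate_random_network",
]

_PROB_TOL = 1e-9


class NetworkValidationError(ValueError):
    """A network definition violates a structural or probabilistic invariant."""


class JointState(NamedTuple):
    """A CSPBN state ``(context, d)``: 1-based context number and GAP index."""

    context: int
    gap: int


# ---------------------------------------------------------------------------
# GAP indexing

def gap_index(bits: Sequence[int]) -> int:
    """Decimal index ``d`` of a GAP bit vector (gene 1 = most significant bit)."""
    bits = list(bits)
    if not bits:
        raise ValueError("GAP bit vector must be nonempty")
    if any(b not in (0, 1) for b in bits):
        raise ValueError(f"GAP bits must be 0/1, got {bits!r}")
    n = len(bits)
    return sum(b << (n - 1 - j) for j, b in enumerate(bits)) + 1


def gap_bits(d: int, n: int) -> tuple[int, ...]:
    """Bit vector of the GAP with decimal index ``d`` in an ``n``-gene network."""
    if not 1 <= d <= (1 << n):
        raise ValueError(f"GAP index {d} out of range 1..{1 << n}")
    g = d - 1
    return tuple((g >> (n - 1 - j)) & 1 for j in range(n))


# ---------------------------------------------------------------------------
# Core types

@dataclass(frozen=True)
class PredictorFunction:
    """One Boolean predictor for a gene.

    Parameters
    ----------
    gene:
        0-based index of the regulated gene.
    inputs:
        Ordered 0-based indices of the input genes; the first input is the
        most significant bit of the truth-table row index.
    table:
        Output bit for every input combination, length ``2**len(inputs)``.
    probability:
        Selection probability ``c`` of this predictor for its gene.
    """

    gene: int
    inputs: tuple[int, ...]
    table: tuple[int, ...]
    probability: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(int(i) for i in self.inputs))
        object.__setattr__(self, "table", tuple(int(t) for t in self.table))
        if len(self.table) != 1 << len(self.inputs):
            raise NetworkValidationError(
                f"gene {self.gene}: table length {len(self.table)} != "
                f"2**{len(self.inputs)} for inputs {self.inputs}"
            )
        if any(t not in (0, 1) for t in self.table):
            raise NetworkValidationError(f"gene {self.gene}: table entries must be 0/1")
        if not 0.0 <= self.probability <= 1.0:
            raise NetworkValidationError(
                f"gene {self.gene}: selection probability {self.probability} not in [0, 1]"
            )

    def evaluate(self, bits: Sequence[int]) -> int:
        """Output bit for the full GAP bit vector ``bits``."""
        m = len(self.inputs)
        row = sum(bits[g] << (m - 1 - t) for t, g in enumerate(self.inputs))
        return self.table[row]

    def outputs(self, n: int) -> np.ndarray:
        """Output bit for every GAP of an ``n``-gene network, as a length-2**n array."""
        gaps = np.arange(1 << n)
        m = len(self.inputs)
        row = np.zeros(1 << n, dtype=np.int64)
        for t, g in enumerate(self.inputs):
            row |= ((gaps >> (n - 1 - g)) & 1) << (m - 1 - t)
        return np.asarray(self.table, dtype=np.uint8)[row]


@dataclass(frozen=True)
class PBNModel:
    """A PBN / CSPBN: genes, per-gene predictor sets, perturbation and switching rates."""

    gene_names: tuple[str, ...]
    functions: tuple[tuple[PredictorFunction, ...], ...]
    perturbation_rate: float = 0.0
    switching_probability: float = 1.0
    topology_incomplete: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "functions", tuple(tuple(fs) for fs in self.functions))
        n = len(self.gene_names)
        if n < 1:
            raise NetworkValidationError("network must have at least one gene")
        if len(set(self.gene_names)) != n:
            raise NetworkValidationError("gene names must be unique")
        if len(self.functions) != n:
            raise NetworkValidationError(
                f"{len(self.functions)} function sets for {n} genes"
            )
        for rate, label in (
            (self.perturbation_rate, "perturbation rate p"),
            (self.switching_probability, "switching probability q"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise NetworkValidationError(f"{label} = {rate} not in [0, 1]")
        for i, fs in enumerate(self.functions):
            if not fs:
                raise NetworkValidationError(f"gene {self.gene_names[i]} has no predictor")
            for f in fs:
                if f.gene != i:
                    raise NetworkValidationError(
                        f"function for gene {f.gene} listed under gene {i}"
                    )
                bad = [g for g in f.inputs if not 0 <= g < n]
                if bad:
                    raise NetworkValidationError(
                        f"gene {self.gene_names[i]}: unknown input gene indices {bad}"
                    )
            total = sum(f.probability for f in fs)
            if abs(total - 1.0) > _PROB_TOL:
                raise NetworkValidationError(
                    f"gene {self.gene_names[i]}: selection probabilities sum to "
                    f"{total!r}, expected 1"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of genes."""
        return len(self.gene_names)

    @property
    def n_states(self) -> int:
        """Number of GAPs, ``2**n``."""
        return 1 << self.n

    @property
    def function_counts(self) -> tuple[int, ...]:
        """``l(i)``: number of predictor functions per gene."""
        return tuple(len(fs) for fs in self.functions)

    @property
    def context_count(self) -> int:
        """``k = prod_i l(i)``: number of contexts (realized Boolean networks)."""
        k = 1
        for c in self.function_counts:
            k *= c
        return k

    @property
    def joint_state_count(self) -> int:
        """Number of joint (context, GAP) states, ``2**n * k``."""
        return self.n_states * self.context_count

    def with_rates(self, p: float | None = None, q: float | None = None) -> "PBNModel":
        """Copy of the model with perturbation and/or switching rates replaced."""
        return replace(
            self,
            perturbation_rate=self.perturbation_rate if p is None else p,
            switching_probability=self.switching_probability if q is None else q,
        )

    def gene_id(self, gene: int | str) -> int:
        """Resolve a gene given by 0-based index or by name."""
        if isinstance(gene, str):
            try:
                return self.gene_names.index(gene)
            except ValueError:
                raise KeyError(f"unknown gene name {gene!r}") from None
        if not 0 <= gene < self.n:
            raise IndexError(f"gene index {gene} out of range 0..{self.n - 1}")
        return int(gene)


@dataclass(frozen=True)
class Context:
    """One realized Boolean network: a predictor choice per gene.

    ``choice[i]`` is the 0-based index of the predictor selected for gene
    ``i``; ``probability`` is the joint selection probability
    ``C = prod_i c_{choice[i]}``.
    """

    choice: tuple[int, ...]
    probability: float

    def next_gap_table(self, model: PBNModel) -> np.ndarray:
        """Deterministic next-GAP lookup over all ``2**n`` GAPs (0-based ints)."""
        n = model.n
        out = np.zeros(1 << n, dtype=np.int64)
        for i, j in enumerate(self.choice):
            out |= model.functions[i][j].outputs(n).astype(np.int64) << (n - 1 - i)
        return out


def enumerate_contexts(model: PBNModel) -> list[Context]:
    """All ``k`` contexts in lexicographic order of per-gene predictor indices.

    The joint selection probabilities multiply the per-function
    probabilities and sum to 1 over the full enumeration.
    """
    contexts = []
    for choice in itertools.product(*(range(l) for l in model.function_counts)):
        prob = 1.0
        for i, j in enumerate(choice):
            prob *= model.functions[i][j].probability
        contexts.append(Context(choice=tuple(choice), probability=prob))
    return contexts


def context_probabilities(model: PBNModel) -> np.ndarray:
    """Vector of the ``k`` context selection probabilities, enumeration order."""
    return np.array([c.probability for c in enumerate_contexts(model)])


def top_context_mass(model: PBNModel, count: int) -> float:
    """Cumulative selection probability of the ``count`` most probable contexts.

    Contexts are sorted by probability descending, ties broken stably by
    enumeration order.
    """
    k = model.context_count
    if not 1 <= count <= k:
        raise ValueError(f"count {count} out of range 1..{k}")
    probs = context_probabilities(model)
    order = np.argsort(-probs, kind="stable")
    return float(probs[order[:count]].sum())


# ---------------------------------------------------------------------------
# Document format

def parse_network(document: dict) -> PBNModel:
    """Build a validated :class:`PBNModel` from a network definition document.

    The document is a mapping with fields ``genes`` (list of names),
    ``functions`` (mapping gene name -> list of ``{inputs, table, prob}``
    with ``table`` a 0/1 string, first input as most significant bit),
    ``p`` and ``q``.  Validation errors are raised; probabilities are never
    silently renormalized.
    """
    try:
        genes = list(document["genes"])
        fun_doc = document["functions"]
        p = float(document["p"])
        q = float(document["q"])
    except (KeyError, TypeError) as exc:
        raise NetworkValidationError(f"malformed network document: {exc}") from exc
    name_to_id = {g: i for i, g in enumerate(genes)}
    functions: list[list[PredictorFunction]] = []
    for i, g in enumerate(genes):
        entries = fun_doc.get(g)
        if not entries:
            raise NetworkValidationError(f"no functions declared for gene {g!r}")
        fs = []
        for entry in entries:
            try:
                inputs = [name_to_id[x] for x in entry["inputs"]]
            except KeyError as exc:
                raise NetworkValidationError(
                    f"gene {g!r}: unknown input gene {exc.args[0]!r}"
                ) from None
            table = str(entry["table"])
            if set(table) - {"0", "1"}:
                raise NetworkValidationError(f"gene {g!r}: non-binary table {table!r}")
            fs.append(
                PredictorFunction(
                    gene=i,
                    inputs=tuple(inputs),
                    table=tuple(int(ch) for ch in table),
                    probability=float(entry["prob"]),
                )
            )
        functions.append(fs)
    return PBNModel(
        gene_names=tuple(genes),
        functions=tuple(tuple(fs) for fs in functions),
        perturbation_rate=p,
        switching_probability=q,
        topology_incomplete=bool(document.get("topology_incomplete", False)),
    )


def load_network(path: str | Path) -> PBNModel:
    """Load a network definition from a YAML (or JSON) document file."""
    with open(path) as fh:
        return parse_network(yaml.safe_load(fh))


def network_to_document(model: PBNModel) -> dict:
    """Inverse of :func:`parse_network`: serialize a model to a plain document."""
    doc: dict = {
        "genes": list(model.gene_names),
        "p": model.perturbation_rate,
        "q": model.switching_probability,
        "functions": {
            g: [
                {
                    "inputs": [model.gene_names[x] for x in f.inputs],
                    "table": "".join(str(t) for t in f.table),
                    "prob": f.probability,
                }
                for f in model.functions[i]
            ]
            for i, g in enumerate(model.gene_names)
        },
    }
    if model.topology_incomplete:
        doc["topology_incomplete"] = True
    return doc


def save_network(model: PBNModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_document(model), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Fixtures

# p53-Mdm2 two-gene PBN: four predictors per gene over inputs (p53, Mdm2),
# truth-table rows ordered 00, 01, 10, 11.  The model captures the mutual
# antagonism that drives the p53-Mdm2 oscillation: p53 tends to rise while
# Mdm2 is low and Mdm2 tends to follow p53.
_P53_TABLES = {
    "p53": [
        ((1, 1, 0, 0), 0.50),
        ((1, 1, 0, 1), 0.40),
        ((1, 0, 1, 1), 0.09),
        ((0, 0, 1, 1), 0.01),
    ],
    "Mdm2": [
        ((0, 0, 1, 1), 0.50),
        ((0, 0, 1, 0), 0.40),
        ((0, 1, 0, 0), 0.09),
        ((1, 1, 0, 0), 0.01),
    ],
}


def build_p53_network(p: float = 0.01, q: float = 0.9) -> PBNModel:
    """The two-gene p53-Mdm2 PBN (16 contexts).

    Defaults put the network in its most-studied operating point:
    perturbation rate ``p = 0.01`` and switching probability ``q = 0.9``.
    """
    names = ("p53", "Mdm2")
    functions = tuple(
        tuple(
            PredictorFunction(gene=i, inputs=(0, 1), table=table, probability=prob)
            for table, prob in _P53_TABLES[name]
        )
        for i, name in enumerate(names)
    )
    return PBNModel(names, functions, perturbation_rate=p, switching_probability=q)


# Per-gene predictor selection probabilities of the 14-gene glioma network
# (gene TOP2A removed).  Six genes are governed by a single predictor, gene 6
# by three, the rest by two; 384 contexts in total.
_GLIOMA_PROBS: tuple[tuple[float, ...], ...] = (
    (0.8560, 0.1440),
    (0.2768, 0.7232),
    (0.6759, 0.3241),
    (1.0,),
    (1.0,),
    (0.0263, 0.4983, 0.4754),
    (1.0,),
    (0.0857, 0.9143),
    (1.0,),
    (1.0,),
    (0.8508, 0.1492),
    (1.0,),
    (0.8697, 0.1303),
    (0.6004, 0.3996),
)

GLIOMA_GENE_NAMES = tuple(f"X{i}" for i in range(1, 15))


def build_glioma_scaffold(
    function_tables: Sequence[Sequence[PredictorFunction]] | None = None,
    p: float = 0.001,
    q: float = 0.99,
) -> PBNModel:
    """The 14-gene glioma network scaffold: published selection probabilities,
    user-supplied Boolean functions.

    The predictor truth tables of this network were inferred from expression
    data and are not part of the scaffold; callers who have them pass one
    list of :class:`PredictorFunction` per gene (counts must match the
    scaffold's per-gene predictor counts, probabilities are taken from the
    scaffold).  Without tables, each predictor defaults to the identity
    function of its own gene and the model is flagged
    ``topology_incomplete``: selection-probability computations (context
    counts, context masses) are exact, but dynamics carry no biological
    meaning.
    """
    names = GLIOMA_GENE_NAMES
    functions: list[tuple[PredictorFunction, ...]] = []
    for i, probs in enumerate(_GLIOMA_PROBS):
        if function_tables is not None:
            supplied = list(function_tables[i])
            if len(supplied) != len(probs):
                raise NetworkValidationError(
                    f"gene {names[i]}: {len(supplied)} tables supplied, "
                    f"scaffold declares {len(probs)} predictors"
                )
            functions.append(
                tuple(
                    replace(f, gene=i, probability=c)
                    for f, c in zip(supplied, probs)
                )
            )
        else:
            functions.append(
                tuple(
                    PredictorFunction(gene=i, inputs=(i,), table=(0, 1), probability=c)
                    for c in probs
                )
            )
    return PBNModel(
        names,
        tuple(functions),
        perturbation_rate=p,
        switching_probability=q,
        topology_incomplete=function_tables is None,
    )


def generate_random_network(
    n: int,
    max_functions: int,
    seed: int,
    p: float = 0.01,
    q: float = 0.9,
) -> PBNModel:
    """Random PBN fixture: random truth tables over all ``n`` inputs,
    per-gene predictor counts in ``1..max_functions``, positive selection
    probabilities normalized to 1.  Identical seeds reproduce identical
    models.
    """
    if n < 1 or max_functions < 1:
        raise ValueError("n and max_functions must be >= 1")
    rng = np.random.default_rng(seed)
    names = tuple(f"g{i + 1}" for i in range(n))
    functions = []
    for i in range(n):
        l_i = int(rng.integers(1, max_functions + 1))
        raw = rng.random(l_i) + 0.05  # bounded away from zero
        probs = raw / raw.sum()
        probs[-1] = 1.0 - probs[:-1].sum()  # exact unit sum
        fs = tuple(
            PredictorFunction(
                gene=i,
                inputs=tuple(range(n)),
                table=tuple(int(b) for b in rng.integers(0, 2, size=1 << n)),
                probability=float(c),
            )
            for c in probs
        )
        functions.append(fs)
    return PBNModel(names, tuple(functions), perturbation_rate=p, switching_probability=q)
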