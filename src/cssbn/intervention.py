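"""External gene intervention: steering the steady state of a PBN.

An intervention designates one *control gene* and an intervention vector
``u`` over all ``2**n`` GAPs: whenever the network lands in a GAP whose
``u`` entry is 1, the control gene's bit is flipped; otherwise the state
passes through unchanged.  Undesirability is a property of the GAP alone —
a GAP is treated identically in every context, since context information is
hidden in practice while expression states are observable.

The default ``flip-on-undesirable`` policy marks exactly the GAPs where a
chosen *target gene* sits at the undesired level.  The module evaluates
candidate control genes by wiring the intervention map into the transition
dynamics (exact mode: composing each context's perturbed matrix with the
intervention map; time-frame mode: an intervention stage in the circuit)
and reporting the steady-state mass of the desirable GAPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exact import (
    Ordering,
    OrderingError,
    SSDOptions,
    StateDistribution,
    joint_transition_matrix,
    marginal_gap_distribution,
    steady_state,
)
from .model import PBNModel, gap_bits, gap_index

__all__ = [
    "InterventionSpec",
    "derive_intervention_vector",
    "apply_intervention",
    "intervention_gap_map",
    "intervention_matrix",
    "desirable_mass",
    "evaluate_control_genes",
]

POLICIES = ("flip-on-undesirable",)


@dataclass(frozen=True)
class InterventionSpec:
    """A single-control-gene intervention.

    ``control_gene`` and ``target_gene`` are 0-based indices; ``u`` is a
    0/1 array indexed by 0-based GAP integer (``d - 1``), 1 marking GAPs
    where the control gene is flipped.
    """

    control_gene: int
    u: np.ndarray
    target_gene: int
    desired_level: int

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=np.uint8)
        object.__setattr__(self, "u", u)
        if set(np.unique(u)) - {0, 1}:
            raise ValueError("intervention vector u must be 0/1")
        if self.desired_level not in (0, 1):
            raise ValueError("desired level must be 0 or 1")

    @property
    def n(self) -> int:
        return int(np.log2(self.u.size))

    def control_vector(self) -> np.ndarray:
        """Indicator vector ``s`` over genes (exactly one 1, the control gene)."""
        s = np.zeros(self.n, dtype=np.uint8)
        s[self.control_gene] = 1
        return s


def derive_intervention_vector(
    model: PBNModel,
    target_gene: int | str,
    desired_level: int,
    control_gene: int | str | None = None,
    policy: str = "flip-on-undesirable",
) -> InterventionSpec:
    """Intervention spec under the named control policy.

    ``flip-on-undesirable`` sets ``u = 1`` exactly on the GAPs where the
    target gene is at the undesired level.  ``control_gene`` defaults to the
    target gene itself (direct control).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    target = model.gene_id(target_gene)
    control = target if control_gene is None else model.gene_id(control_gene)
    if desired_level not in (0, 1):
        raise ValueError("desired level must be 0 or 1")
    n = model.n
    gaps = np.arange(1 << n)
    target_bit = (gaps >> (n - 1 - target)) & 1
    u = (target_bit != desired_level).astype(np.uint8)
    return InterventionSpec(
        control_gene=control, u=u, target_gene=target, desired_level=desired_level
    )


def intervention_gap_map(spec: InterventionSpec, n: int) -> np.ndarray:
    """Deterministic GAP map of the intervention: index ``g`` -> index after control.

    Flips the control gene's bit on GAPs with ``u = 1``; an involution
    whenever ``u`` is symmetric under that flip.
    """
    if spec.u.size != 1 << n:
        raise ValueError(f"u has {spec.u.size} entries for n={n}")
    gaps = np.arange(1 << n)
    flip = 1 << (n - 1 - spec.control_gene)
    return np.where(spec.u.astype(bool), gaps ^ flip, gaps)


def intervention_matrix(spec: InterventionSpec, n: int) -> np.ndarray:
    """0/1 matrix form of :func:`intervention_gap_map` (rows = pre-control GAPs)."""
    m = 1 << n
    mat = np.zeros((m, m))
    mat[np.arange(m), intervention_gap_map(spec, n)] = 1.0
    return mat


def apply_intervention(
    gap: Sequence[int] | int, spec: InterventionSpec
) -> tuple[int, ...] | int:
    """Apply the control action to one GAP.

    Accepts a bit vector (returns a bit vector) or a 1-based decimal index
    ``d`` (returns the new ``d``).  At most one bit — the control gene's —
    ever changes.
    """
    if isinstance(gap, (int, np.integer)):
        n = spec.n
        mapped = intervention_gap_map(spec, n)[int(gap) - 1]
        return int(mapped) + 1
    bits = list(gap)
    d = gap_index(bits)
    if spec.u[d - 1]:
        bits[spec.control_gene] ^= 1
    return tuple(bits)


def desirable_mass(
    ssd: StateDistribution, target_gene: int, desired_level: int
) -> float:
    """Steady-state probability of the GAPs with the target gene at its desired level."""
    if ssd.ordering.is_joint:
        raise OrderingError("desirable_mass expects a GAP-ordered distribution")
    n = ssd.ordering.n
    gaps = np.arange(1 << n)
    level = (gaps >> (n - 1 - target_gene)) & 1
    return float(ssd.probs[level == desired_level].sum())


def evaluate_control_genes(
    model: PBNModel,
    target_gene: int | str,
    desired_level: int,
    engine: str = "exact",
    candidates: Sequence[int | str] | None = None,
    options: SSDOptions | None = None,
    length: int = 10_000,
    seed: int = 0,
    force: bool = False,
) -> pd.DataFrame:
    """Desirable steady-state mass for each candidate control gene.

    Rows: a no-intervention baseline, then one row per candidate control
    gene (all genes by default, so the direct control of the target is
    included).  ``engine="exact"`` solves the intervened joint chain
    analytically; ``engine="time-frame"`` runs the stochastic circuit with
    an intervention stage, using ``length`` lanes and ``seed``.

    Refuses topology-incomplete scaffolds unless ``force=True``: their
    placeholder dynamics would make the ranking meaningless.
    """
    if engine not in ("exact", "time-frame"):
        raise ValueError(f"unknown engine {engine!r}")
    if model.topology_incomplete and not force:
        raise ValueError(
            "model is a topology-incomplete scaffold; its dynamics are "
            "placeholders — pass force=True to rank control genes anyway"
        )
    target = model.gene_id(target_gene)
    if candidates is None:
        candidate_ids = list(range(model.n))
    else:
        candidate_ids = [model.gene_id(c) for c in candidates]

    def gap_ssd(spec: InterventionSpec | None) -> StateDistribution:
        if engine == "exact":
            imap = None if spec is None else intervention_gap_map(spec, model.n)
            tm = joint_transition_matrix(model, intervention_map=imap)
            return marginal_gap_distribution(
                steady_state(tm, options).distribution
            )
        from .circuit import build_cssbn  # local import; circuit depends on this module

        circ = build_cssbn(model, length=length, source=seed, intervention=spec)
        return marginal_gap_distribution(circ.estimate_ssd_time_frame(options).distribution)

    rows = [
        {
            "control": "(none)",
            "desirable_mass": desirable_mass(gap_ssd(None), target, desired_level),
        }
    ]
    for gid in candidate_ids:
        spec = derive_intervention_vector(
            model, target, desired_level, control_gene=gid
        )
        rows.append(
            {
                "control": model.gene_names[gid],
                "desirable_mass": desirable_mass(gap_ssd(spec), target, desired_level),
            }
        )
    return pd.DataFrame(rows)
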