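"""Delimited-text writers and readers for matrices and distributions.

Matrices are written as tab-separated tables with a header row and a
leading column of state labels (``d`` for GAP ordering, ``(ctx,d)`` for
joint ordering); distributions as two-column tables (state label,
probability).  A transposed matrix writer is provided for consumers who
prefer columns-as-source orientation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exact import Ordering, StateDistribution, TransitionMatrix

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_distribution",
    "read_distribution",
]


def write_matrix(
    matrix: TransitionMatrix, path: str | Path, transpose: bool = False
) -> None:
    """Write a transition matrix as labeled tab-separated text.

    Rows are source states unless ``transpose`` is set.
    """
    labels = matrix.ordering.labels()
    entries = matrix.entries.T if transpose else matrix.entries
    frame = pd.DataFrame(entries, index=labels, columns=labels)
    frame.to_csv(path, sep="\t", index_label="state", float_format="%.12g")


def _ordering_from_labels(labels: list[str]) -> Ordering:
    if labels[-1].startswith("("):
        s, d = labels[-1].strip("()").split(",")
        return Ordering(n=int(np.log2(int(d))), k=int(s))
    return Ordering(n=int(np.log2(int(labels[-1]))))


def read_matrix(path: str | Path) -> TransitionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return TransitionMatrix(
        frame.to_numpy(dtype=float), _ordering_from_labels(list(frame.index.astype(str)))
    )


def write_distribution(dist: StateDistribution, path: str | Path) -> None:
    """Write a distribution as two-column tab-separated text (label, probability)."""
    frame = pd.DataFrame(
        {"state": dist.ordering.labels(), "probability": dist.probs}
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_distribution(path: str | Path) -> StateDistribution:
    frame = pd.read_csv(path, sep="\t")
    return StateDistribution(
        frame["probability"].to_numpy(dtype=float),
        _ordering_from_labels(list(frame["state"].astype(str))),
    )
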