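"""Shannon entropy and information gain on two-class contingency tables.

The compound screen and the functional-state evaluation both reduce to the
same primitive: a population of items carrying one of two class labels is
split into two branches, and the split is scored by the information gain

    IG(T, X) = Entropy(T) - sum_s (|s| / |T|) * Entropy(s)

with entropies in bits (log base 2) and the convention 0 * log2(0) = 0.
For a 2x2 branch-by-class table this equals the mutual information between
branch and class. One implementation serves both label alphabets
({ru, pd} for the compound screen, {p, n} for state directions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["shannon_entropy", "information_gain", "InformationGain"]


def shannon_entropy(counts) -> float:
    """Shannon entropy, in bits, of the label distribution given by ``counts``.

    Parameters
    ----------
    counts
        Sequence of nonnegative class counts (any length >= 1). Zero counts
        contribute nothing (0 * log2 0 = 0 convention).

    Returns
    -------
    float
        Entropy in bits; for two classes this lies in [0, 1].

    Raises
    ------
    ValueError
        If counts are negative, non-finite, or all zero (an empty population
        has no defined entropy).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(c)) or np.any(c < 0):
        raise ValueError("counts must be finite and nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("entropy undefined: all counts are zero")
    p = c / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


@dataclass(frozen=True)
class InformationGain:
    """Decomposition of an information-gain computation on a 2x2 table.

    ``table`` has rows = branches (up, down) and columns = classes; all
    entropies are in bits.
    """

    table: np.ndarray
    entropy_parent: float
    branch_entropies: tuple[float, float]
    weighted_child_entropy: float
    ig: float


def information_gain(table) -> InformationGain:
    """Information gain of the branch split recorded in a 2x2 count table.

    Rows are the two branches of the split (e.g. up-/down-regulated), columns
    the two class labels (e.g. ru/pd or p/n). An empty branch contributes
    zero weighted entropy. Equals the mutual information of the table.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("table entries must be finite and nonnegative")
    total = t.sum()
    if total == 0:
        raise ValueError("information gain undefined on an empty table")

    h_parent = shannon_entropy(t.sum(axis=0))
    branch_h = []
    weighted = 0.0
    for row in t:
        n = row.sum()
        h = shannon_entropy(row) if n > 0 else 0.0
        branch_h.append(h)
        weighted += (n / total) * h
    ig = h_parent - weighted
    if ig < 0:  # float round-off only; IG is nonnegative by Jensen
        ig = 0.0
    return InformationGain(
        table=t,
        entropy_parent=h_parent,
        branch_entropies=(branch_h[0], branch_h[1]),
        weighted_child_entropy=weighted,
        ig=ig,
    )
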