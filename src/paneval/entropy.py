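"""Objective indicator weights from information entropy.

Each column is min-max normalized (direction-aware), converted to a
within-column proportion distribution, and scored by Shannon entropy with the
``0 * ln 0 := 0`` convention.  Less entropic (more discriminating) indicators
receive larger weights: ``W_j = (1 - e_j) / sum_j (1 - e_j)``.

Constant columns carry no discriminating information; by convention they get
entropy 1, redundancy 0 and weight 0, and the remaining weights renormalize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateColumnError, DomainError
from .normalize import minmax_normalize
from .panel import IndicatorPanel

__all__ = [
    "EntropyWeightResult",
    "proportions",
    "entropy",
    "weights_from_redundancy",
    "compute_entropy_weights",
]


@dataclass(frozen=True)
class EntropyWeightResult:
    """All intermediate matrices of the entropy-weight computation."""

    indicators: tuple[str, ...]
    normalized: np.ndarray  # n x m, min-max with direction folded in
    proportions: np.ndarray  # n x m, columns sum to 1 (NaN for degenerate columns)
    entropies: np.ndarray  # m
    redundancies: np.ndarray  # m, = 1 - entropies
    weights: np.ndarray  # m, sums to 1

    def weight_of(self, indicator: str) -> float:
        return float(self.weights[self.indicators.index(indicator)])


def proportions(normalized: np.ndarray) -> np.ndarray:
    """Column-wise proportions ``p_ij = a_ij / sum_i a_ij``."""
    a = np.asarray(normalized, dtype=float)
    if np.any(a < 0):
        raise DomainError("proportions require non-negative entries")
    sums = a.sum(axis=0)
    if np.any(sums <= 0):
        raise DegenerateColumnError("zero-sum column has no proportion distribution")
    return a / sums


def entropy(proportions_column, n: int | None = None) -> float:
    """Normalized Shannon entropy of one proportion column.

    ``e = -(1/ln n) * sum_i p_i ln p_i`` with ``0 * ln 0 := 0``.  ``n``
    defaults to the column length; the result lies in [0, 1] with 1 for the
    uniform distribution and 0 for a point mass.
    """
    p = np.asarray(proportions_column, dtype=float)
    if np.any(p < 0):
        raise DomainError("proportions must be non-negative")
    if n is None:
        n = p.size
    if n < 2:
        raise DomainError("entropy needs at least two alternatives")
    # math.fsum keeps the accumulation error at one ulp
    s = math.fsum(float(pi) * math.log(pi) for pi in p if pi > 0.0)
    return -s / math.log(n)


def weights_from_redundancy(redundancies) -> np.ndarray:
    """Normalize redundancies ``d_j = 1 - e_j`` into weights summing to 1."""
    d = np.asarray(redundancies, dtype=float)
    if np.any(d < 0):
        raise DomainError("redundancies must be non-negative")
    total = d.sum()
    if total <= 0:
        raise DomainError("all redundancies are zero: the panel carries no information")
    return d / total


def compute_entropy_weights(panel: IndicatorPanel) -> EntropyWeightResult:
    """Run the full entropy-weight chain on a panel.

    Consumes the *raw* values with each indicator's direction flag (the
    min-max step already makes columns comparable, so no co-trend is applied
    first).  Degenerate (constant) columns get entropy 1 and weight 0.
    """
    n, m = panel.values.shape
    normalized = np.empty((n, m))
    props = np.full((n, m), np.nan)
    entropies = np.empty(m)
    for j in range(m):
        try:
            normalized[:, j] = minmax_normalize(panel.values[:, j], panel.directions[j])
        except DegenerateColumnError:
            normalized[:, j] = 0.0
            entropies[j] = 1.0  # no information
            continue
        props[:, j] = proportions(normalized[:, j].reshape(n, 1))[:, 0]
        entropies[j] = entropy(props[:, j], n)
    redundancies = 1.0 - entropies
    weights = weights_from_redundancy(redundancies)
    return EntropyWeightResult(
        indicators=panel.indicators,
        normalized=normalized,
        proportions=props,
        entropies=entropies,
        redundancies=redundancies,
        weights=weights,
    )
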