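"""Weighted rank-sum ratio scoring with midrank tie handling.

Each indicator column is replaced by within-column ranks 1..n where n is the
*best* alternative (benefit columns rank ascending values, cost columns
descending ones); exact ties receive the arithmetic mean of their positional
ranks (midranks).  Scores:

* ``RSR_i  = (1/(m*n)) * sum_j R_ij``       (unweighted)
* ``WRSR_i = (1/n) * sum_j W_j * R_ij``     (indicator-weighted)

Larger scores are better.  Being rank-based, both are invariant under any
strictly monotone transform of a raw column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from ._ranking import rank_descending
from .errors import DomainError, ValidationError
from .panel import BENEFIT, COST, IndicatorPanel

__all__ = [
    "RsrResult",
    "midrank_column",
    "rsr_scores",
    "wrsr_scores",
    "evaluate_rsr",
]


@dataclass(frozen=True)
class RsrResult:
    alternatives: tuple[str, ...]
    rank_matrix: np.ndarray  # n x m midranks, n = best per column
    rsr: np.ndarray  # n
    wrsr: np.ndarray  # n
    ranks: np.ndarray  # n, permutation of 1..n, 1 = best (by WRSR)

    def wrsr_of(self, alternative: str) -> float:
        return float(self.wrsr[self.alternatives.index(str(alternative))])

    def rank_of(self, alternative: str) -> int:
        return int(self.ranks[self.alternatives.index(str(alternative))])


def midrank_column(values, direction: str) -> np.ndarray:
    """Within-column midranks, oriented so the best value gets rank n."""
    x = np.asarray(values, dtype=float)
    if direction == BENEFIT:
        return rankdata(x, method="average")
    if direction == COST:
        return rankdata(-x, method="average")
    raise ValidationError(f"unknown direction {direction!r}")


def rsr_scores(rank_matrix) -> np.ndarray:
    """Unweighted rank-sum ratio per row: ``(1/(m*n)) * sum_j R_ij``."""
    r = np.asarray(rank_matrix, dtype=float)
    n, m = r.shape
    return r.sum(axis=1) / (m * n)


def wrsr_scores(rank_matrix, weights) -> np.ndarray:
    """Weighted rank-sum ratio per row: ``(1/n) * sum_j W_j * R_ij``."""
    r = np.asarray(rank_matrix, dtype=float)
    w = np.asarray(weights, dtype=float)
    n, m = r.shape
    if w.size != m:
        raise DomainError(f"{w.size} weights for {m} rank columns")
    return (r @ w) / n


def evaluate_rsr(panel: IndicatorPanel, weights) -> RsrResult:
    """Rank every column, score, and order alternatives by WRSR."""
    n, m = panel.values.shape
    rank_matrix = np.empty((n, m))
    for j in range(m):
        rank_matrix[:, j] = midrank_column(panel.values[:, j], panel.directions[j])
    wrsr = wrsr_scores(rank_matrix, weights)
    return RsrResult(
        alternatives=panel.alternatives,
        rank_matrix=rank_matrix,
        rsr=rsr_scores(rank_matrix),
        wrsr=wrsr,
        ranks=rank_descending(wrsr),
    )
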