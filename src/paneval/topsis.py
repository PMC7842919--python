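"""Weighted TOPSIS: closeness of each alternative to the ideal solution.

Pipeline: co-trend cost columns (reciprocal by default), scale every column
to unit Euclidean norm, multiply by the indicator weights, read the ideal
vector A+ (column maxima) and anti-ideal A- (column minima) off the weighted
matrix, and score each alternative by ``C = D- / (D+ + D-)`` where ``D+``
and ``D-`` are Euclidean distances to A+ and A-.  ``C`` is 1 exactly on the
ideal profile and 0 exactly on the anti-ideal one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._ranking import rank_descending
from .errors import DomainError
from .normalize import CotrendConfig, cotrend_column, vector_normalize
from .panel import COST, IndicatorPanel

__all__ = [
    "TopsisResult",
    "weighted_normalized",
    "distances",
    "closeness",
    "rank_topsis",
    "evaluate_topsis",
]


@dataclass(frozen=True)
class TopsisResult:
    alternatives: tuple[str, ...]
    weighted_matrix: np.ndarray  # n x m
    ideal: np.ndarray  # m, column maxima (A+)
    anti_ideal: np.ndarray  # m, column minima (A-)
    d_plus: np.ndarray  # n, distance to A+
    d_minus: np.ndarray  # n, distance to A-
    closeness: np.ndarray  # n, in [0, 1]
    ranks: np.ndarray  # n, permutation of 1..n, 1 = best

    def closeness_of(self, alternative: str) -> float:
        return float(self.closeness[self.alternatives.index(str(alternative))])

    def rank_of(self, alternative: str) -> int:
        return int(self.ranks[self.alternatives.index(str(alternative))])


def _cotrend_config(panel: IndicatorPanel, j: int) -> CotrendConfig:
    spec = panel.schema[j]
    return CotrendConfig(method=spec.cotrend_method, reference=spec.cost_reference)


def weighted_normalized(panel: IndicatorPanel, weights) -> np.ndarray:
    """Co-trend cost columns, vector-normalize and weight every column."""
    w = np.asarray(weights, dtype=float)
    if w.size != panel.n_indicators:
        raise DomainError(
            f"{w.size} weights for {panel.n_indicators} indicators"
        )
    if not np.isclose(w.sum(), 1.0):
        raise DomainError(f"weights must sum to 1, got {w.sum()}")
    out = np.empty_like(panel.values, dtype=float)
    for j in range(panel.n_indicators):
        col = panel.values[:, j]
        if panel.schema[j].direction == COST:
            col = cotrend_column(col, _cotrend_config(panel, j))
        out[:, j] = vector_normalize(col) * w[j]
    return out


def distances(weighted: np.ndarray, ideal, anti_ideal) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance of every row to the ideal and anti-ideal vectors."""
    z = np.asarray(weighted, dtype=float)
    a_plus = np.asarray(ideal, dtype=float)
    a_minus = np.asarray(anti_ideal, dtype=float)
    if z.shape[1] != a_plus.size or z.shape[1] != a_minus.size:
        raise DomainError("dimension mismatch between matrix and ideal vectors")
    d_plus = np.sqrt(((z - a_plus) ** 2).sum(axis=1))
    d_minus = np.sqrt(((z - a_minus) ** 2).sum(axis=1))
    return d_plus, d_minus


def closeness(d_plus, d_minus) -> np.ndarray:
    """Relative closeness ``C = D- / (D+ + D-)``; 0.5 where both are zero."""
    dp = np.asarray(d_plus, dtype=float)
    dm = np.asarray(d_minus, dtype=float)
    total = dp + dm
    degenerate = total == 0.0
    if np.any(degenerate):
        warnings.warn(
            "alternative coincides with both ideal and anti-ideal "
            "(all alternatives identical?); closeness set to 0.5",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, total)
    return np.where(degenerate, 0.5, dm / safe)


def rank_topsis(closeness_values) -> np.ndarray:
    """Descending ranks of the closeness coefficients (1 = best)."""
    return rank_descending(closeness_values)


def evaluate_topsis(panel: IndicatorPanel, weights) -> TopsisResult:
    """Full TOPSIS run on a panel with the given indicator weights."""
    z = weighted_normalized(panel, weights)
    ideal = z.max(axis=0)
    anti_ideal = z.min(axis=0)
    d_plus, d_minus = distances(z, ideal, anti_ideal)
    c = closeness(d_plus, d_minus)
    return TopsisResult(
        alternatives=panel.alternatives,
        weighted_matrix=z,
        ideal=ideal,
        anti_ideal=anti_ideal,
        d_plus=d_plus,
        d_minus=d_minus,
        closeness=c,
        ranks=rank_topsis(c),
    )
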