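"""Fuzzy comprehensive evaluation: convex combinations of two score vectors.

The TOPSIS closeness coefficients and the WRSR scores are blended as
``W1 * C + W2 * WRSR`` under several weight-ratio schemes (default 0.1:0.9,
0.5:0.5, 0.9:0.1), each scheme is ranked, and every alternative receives the
rank that occurs most often across schemes.  When no strict mode exists the
rank under the most balanced scheme (closest to 0.5:0.5) breaks the tie.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._ranking import rank_descending
from .errors import DomainError

__all__ = ["DEFAULT_RATIO_SCHEMES", "FuzzyResult", "combine", "comprehensive_rank", "evaluate_fuzzy"]

DEFAULT_RATIO_SCHEMES: tuple[tuple[float, float], ...] = (
    (0.1, 0.9),
    (0.5, 0.5),
    (0.9, 0.1),
)


@dataclass(frozen=True)
class FuzzyResult:
    alternatives: tuple[str, ...]
    ratio_schemes: tuple[tuple[float, float], ...]
    scores: np.ndarray  # n x k
    scheme_ranks: np.ndarray  # n x k, each column a permutation of 1..n
    comprehensive_rank: np.ndarray  # n

    def rank_of(self, alternative: str) -> int:
        return int(self.comprehensive_rank[self.alternatives.index(str(alternative))])


def _check_ratio(ratio: Sequence[float]) -> tuple[float, float]:
    w1, w2 = float(ratio[0]), float(ratio[1])
    if w1 < 0 or w2 < 0 or abs(w1 + w2 - 1.0) > 1e-9:
        raise DomainError(f"ratio ({w1}, {w2}) must be non-negative and sum to 1")
    return w1, w2


def combine(closeness, wrsr, ratio: Sequence[float]) -> np.ndarray:
    """Elementwise convex combination ``W1 * closeness + W2 * wrsr``."""
    w1, w2 = _check_ratio(ratio)
    c = np.asarray(closeness, dtype=float)
    r = np.asarray(wrsr, dtype=float)
    if c.shape != r.shape:
        raise DomainError("score vectors differ in length")
    return w1 * c + w2 * r


def comprehensive_rank(
    scheme_ranks, ratio_schemes: Sequence[Sequence[float]] | None = None
) -> np.ndarray:
    """Modal rank of each alternative across schemes.

    With no strict mode (all scheme ranks distinct), fall back to the scheme
    whose ratio is closest to (0.5, 0.5); ``ratio_schemes`` orders that
    choice and defaults to :data:`DEFAULT_RATIO_SCHEMES`.
    """
    ranks = np.asarray(scheme_ranks, dtype=float)
    if ranks.ndim != 2 or ranks.shape[1] < 1:
        raise DomainError("scheme_ranks must be an n x k matrix with k >= 1")
    if ratio_schemes is None:
        ratio_schemes = DEFAULT_RATIO_SCHEMES
    if len(ratio_schemes) != ranks.shape[1]:
        raise DomainError("one ratio scheme required per rank column")
    fallback_col = int(
        np.argmin([abs(float(r[0]) - 0.5) for r in ratio_schemes])
    )
    out = np.empty(ranks.shape[0], dtype=int)
    for i, row in enumerate(ranks):
        values, counts = np.unique(row, return_counts=True)
        top = counts.max()
        if top > 1 and (counts == top).sum() == 1:
            out[i] = int(values[np.argmax(counts)])
        else:
            out[i] = int(row[fallback_col])
    return out


def evaluate_fuzzy(
    alternatives: Sequence[str],
    closeness,
    wrsr,
    ratio_schemes: Sequence[Sequence[float]] = DEFAULT_RATIO_SCHEMES,
) -> FuzzyResult:
    """Score and rank every ratio scheme, then take the modal rank."""
    schemes = tuple((_check_ratio(r)) for r in ratio_schemes)
    scores = np.column_stack([combine(closeness, wrsr, r) for r in schemes])
    scheme_ranks = np.column_stack([rank_descending(scores[:, k]) for k in range(len(schemes))])
    return FuzzyResult(
        alternatives=tuple(str(a) for a in alternatives),
        ratio_schemes=schemes,
        scores=scores,
        scheme_ranks=scheme_ranks,
        comprehensive_rank=comprehensive_rank(scheme_ranks, schemes),
    )
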