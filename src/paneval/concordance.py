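"""Spearman rank correlation between method rankings.

Without ties the classic shortcut ``rho = 1 - 6*sum(d^2) / (n*(n^2-1))`` is
exact; with ties the product-moment correlation of midranks is used instead.
The p-value comes from the usual t approximation with ``n - 2`` degrees of
freedom (two-sided).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, t as t_dist

from .errors import DomainError

__all__ = ["ConcordanceResult", "spearman"]


@dataclass(frozen=True)
class ConcordanceResult:
    method_pair: tuple[str, str]
    rho: float
    sum_d2: float
    p_value: float


def spearman(ranks_a, ranks_b, method_pair: tuple[str, str] = ("a", "b")) -> ConcordanceResult:
    """Spearman correlation of two equally long score/rank vectors."""
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("inputs must be 1-d vectors of equal length")
    n = a.size
    if n < 3:
        raise DomainError("need at least 3 observations")
    ra = rankdata(a, method="average")
    rb = rankdata(b, method="average")
    if np.all(ra == ra[0]) or np.all(rb == rb[0]):
        raise DomainError("constant vector: Spearman correlation undefined")
    d2 = float(((ra - rb) ** 2).sum())
    ties = (np.unique(ra).size < n) or (np.unique(rb).size < n)
    if ties:
        # shortcut formula is exact only without ties
        rho = float(np.corrcoef(ra, rb)[0, 1])
    else:
        rho = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t_stat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
    return ConcordanceResult(
        method_pair=(str(method_pair[0]), str(method_pair[1])),
        rho=rho,
        sum_d2=d2,
        p_value=p,
    )
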