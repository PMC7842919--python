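"""Co-trending and the two column normalizations used by the pipeline.

Co-trending turns a cost (smaller-is-better) column into a benefit
(larger-is-better) one, either by subtracting from a reference value
(``difference``) or by taking reciprocals (``reciprocal``).

Two distinct normalizations coexist downstream and must not be conflated:

* :func:`minmax_normalize` feeds the entropy-weight stage and already folds
  in the indicator direction, so it consumes *raw* columns.
* :func:`vector_normalize` (unit Euclidean norm) feeds the TOPSIS stage and
  expects an already co-trended, larger-is-better column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateColumnError, DomainError, ValidationError
from .panel import BENEFIT, COST

__all__ = [
    "CotrendConfig",
    "cotrend_column",
    "minmax_normalize",
    "vector_normalize",
]


@dataclass(frozen=True)
class CotrendConfig:
    """How to convert a cost column to larger-is-better.

    ``method="difference"`` computes ``reference - x`` and requires
    ``reference`` to exceed every column value; ``method="reciprocal"``
    computes ``1/x`` and requires strictly positive values.
    """

    method: str = "reciprocal"
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("difference", "reciprocal"):
            raise ValidationError(f"unknown co-trend method {self.method!r}")
        if self.method == "difference" and self.reference is None:
            raise ValidationError("difference co-trend requires a reference value")


def cotrend_column(values, cfg: CotrendConfig) -> np.ndarray:
    """Convert one cost column to larger-is-better, preserving order reversal."""
    x = np.asarray(values, dtype=float)
    if cfg.method == "difference":
        ref = float(cfg.reference)  # type: ignore[arg-type]
        if ref <= x.max():
            raise DomainError(
                f"difference reference {ref} must exceed the column maximum {x.max()}"
            )
        return ref - x
    if np.any(x <= 0):
        raise DomainError("reciprocal co-trend requires strictly positive values")
    return 1.0 / x


def minmax_normalize(values, direction: str) -> np.ndarray:
    """Min-max normalize one column to [0, 1], folding in its direction.

    Benefit columns map through ``(x - min) / (max - min)``, cost columns
    through ``(max - x) / (max - min)``; either way the best value maps to 1
    and the worst to 0.  A constant column has no spread to normalize and
    raises :class:`DegenerateColumnError` so the caller can decide (the
    entropy stage assigns such columns zero weight).
    """
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateColumnError("constant column cannot be min-max normalized")
    if direction == BENEFIT:
        return (x - lo) / (hi - lo)
    if direction == COST:
        return (hi - x) / (hi - lo)
    raise ValidationError(f"unknown direction {direction!r}")


def vector_normalize(values) -> np.ndarray:
    """Scale one column to unit Euclidean norm (``x / sqrt(sum x^2)``)."""
    x = np.asarray(values, dtype=float)
    norm = float(np.sqrt(np.sum(x * x)))
    if norm == 0.0:
        raise DomainError("all-zero column cannot be vector normalized")
    return x / norm
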