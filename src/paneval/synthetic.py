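"""Seeded generator for synthetic indicator panels.

Panels mimic an ordered time series of health indicators: each column is a
roughly monotone linear trend plus truncated Gaussian noise, with benefit
columns trending up and cost columns trending down, plus an optional
probability of copying the previous alternative's value to create exact ties
(so midrank handling is exercised).  Cost columns are kept strictly positive
so the reciprocal co-trend stays admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, ValidationError
from .panel import BENEFIT, COST, IndicatorPanel, IndicatorSchema

__all__ = ["SyntheticIndicator", "SyntheticSpec", "generate"]

_POSITIVE_FLOOR = 1e-9


@dataclass(frozen=True)
class SyntheticIndicator:
    """One synthetic column: linear trend plus noise."""

    label: str
    direction: str = BENEFIT
    start: float = 50.0
    trend: float = 1.0  # magnitude of per-step improvement
    noise: float = 0.0  # Gaussian sigma
    tie_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in (BENEFIT, COST):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if self.noise < 0:
            raise ValidationError("noise scale must be >= 0")
        if not 0.0 <= self.tie_prob < 1.0:
            raise ValidationError("tie probability must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    n_alternatives: int = 15
    indicators: tuple[SyntheticIndicator, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alternatives < 2:
            raise ValidationError("need at least 2 alternatives")
        if not self.indicators:
            raise ValidationError("need at least 1 indicator")
        object.__setattr__(self, "indicators", tuple(self.indicators))


def generate(spec: SyntheticSpec) -> IndicatorPanel:
    """Generate a panel deterministically from ``spec.seed``.

    ``value(i, j) = start_j +/- i * trend_j + noise`` where the sign of the
    trend improves over the alternative index (up for benefit, down for
    cost).  Noise on cost columns is truncated so values stay positive; a
    spec whose deterministic part already reaches zero raises.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_alternatives
    m = len(spec.indicators)
    values = np.empty((n, m))
    for j, ind in enumerate(spec.indicators):
        step = abs(ind.trend) if ind.direction == BENEFIT else -abs(ind.trend)
        base = ind.start + step * np.arange(n)
        if ind.direction == COST and base.min() <= 0:
            raise DomainError(
                f"indicator {ind.label!r}: deterministic trend reaches a "
                "non-positive value; shrink the trend or raise the start level"
            )
        col = base + rng.normal(0.0, ind.noise, size=n) if ind.noise > 0 else base.copy()
        if ind.direction == COST:
            # truncate noise so the reciprocal co-trend stays defined
            col = np.maximum(col, base * 0.01 + _POSITIVE_FLOOR)
        if ind.tie_prob > 0:
            duplicate = rng.random(n - 1) < ind.tie_prob
            for i in np.flatnonzero(duplicate) + 1:
                col[i] = col[i - 1]
        values[:, j] = col

    schema = tuple(
        IndicatorSchema(
            direction=ind.direction,
            cost_reference=(
                float(np.ceil(values[:, j].max() * 2 + 1)) if ind.direction == COST else None
            ),
            cotrend_method="reciprocal",
        )
        for j, ind in enumerate(spec.indicators)
    )
    return IndicatorPanel(
        alternatives=tuple(f"A{i + 1:02d}" for i in range(n)),
        indicators=tuple(ind.label for ind in spec.indicators),
        values=values,
        schema=schema,
    )
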