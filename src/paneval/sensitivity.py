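"""Weight-perturbation sensitivity analysis of the TOPSIS ranking.

One indicator weight is perturbed at a time.  The unitary variation rate
``beta`` prescribes the perturbed weight's *final* (post-renormalization)
value, ``W'_k = beta * W_k``; the raw pre-normalization multiplier that
achieves this is ``gamma = (beta - beta*W_k) / (1 - beta*W_k)``.  The other
weights are scaled by the common renormalization, so their pairwise ratios
are preserved.  For every beta on a grid the full TOPSIS closeness vector is
recomputed, giving one closeness curve per alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError
from .panel import IndicatorPanel
from .topsis import evaluate_topsis

__all__ = [
    "DEFAULT_BETA_GRID",
    "SensitivitySweep",
    "gamma_from_beta",
    "perturb_weights",
    "sweep",
    "rank_crossings",
]

DEFAULT_BETA_GRID: tuple[float, ...] = (
    0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5,
)


@dataclass(frozen=True)
class SensitivitySweep:
    alternatives: tuple[str, ...]
    perturbed_index: int
    betas: tuple[float, ...]
    gammas: np.ndarray  # per beta
    weight_vectors: np.ndarray  # len(betas) x m
    closeness_matrix: np.ndarray  # len(betas) x n
    rank_matrix: np.ndarray  # len(betas) x n


def gamma_from_beta(beta: float, weight: float) -> float:
    """Raw multiplier achieving final weight ratio ``beta`` after renormalization."""
    beta = float(beta)
    w = float(weight)
    if not 0.0 < w < 1.0:
        raise DomainError(f"weight must lie in (0, 1), got {w}")
    if beta <= 0.0:
        raise DomainError(f"beta must be positive, got {beta}")
    if beta * w >= 1.0:
        raise DomainError(
            f"beta * weight = {beta * w} >= 1: perturbed weight would reach 1"
        )
    return (beta - beta * w) / (1.0 - beta * w)


def perturb_weights(weights, k: int, beta: float) -> np.ndarray:
    """Scale weight ``k`` by ``gamma_from_beta`` and renormalize the vector.

    The result satisfies ``out[k] == beta * weights[k]`` exactly (up to
    floating point) and preserves the pairwise ratios of the other weights.
    """
    w = np.asarray(weights, dtype=float)
    if not 0 <= k < w.size:
        raise DomainError(f"indicator index {k} out of range for {w.size} weights")
    gamma = gamma_from_beta(beta, w[k])
    perturbed = w.copy()
    perturbed[k] = gamma * w[k]
    return perturbed / perturbed.sum()


def sweep(
    panel: IndicatorPanel,
    weights,
    k: int,
    betas: Sequence[float] = DEFAULT_BETA_GRID,
) -> SensitivitySweep:
    """Recompute TOPSIS closeness and ranks under each perturbed weight vector."""
    w = np.asarray(weights, dtype=float)
    betas = tuple(float(b) for b in betas)
    if not betas:
        raise DomainError("beta grid is empty")
    gammas = np.array([gamma_from_beta(b, w[k]) for b in betas])
    weight_vectors = np.vstack([perturb_weights(w, k, b) for b in betas])
    closeness_rows = []
    rank_rows = []
    for wv in weight_vectors:
        res = evaluate_topsis(panel, wv)
        closeness_rows.append(res.closeness)
        rank_rows.append(res.ranks)
    return SensitivitySweep(
        alternatives=panel.alternatives,
        perturbed_index=int(k),
        betas=betas,
        gammas=gammas,
        weight_vectors=weight_vectors,
        closeness_matrix=np.vstack(closeness_rows),
        rank_matrix=np.vstack(rank_rows),
    )


def rank_crossings(
    sweep_result: SensitivitySweep,
) -> list[tuple[tuple[str, str], tuple[float, float]]]:
    """Alternative pairs whose relative order flips between grid points.

    Returns ``[((alt_a, alt_b), (beta_lo, beta_hi)), ...]`` for every pair
    whose rank order differs between two consecutive betas on the grid.
    """
    betas = sweep_result.betas
    if len(betas) < 2:
        raise DomainError("need at least two beta values to detect crossings")
    ranks = sweep_result.rank_matrix
    alts = sweep_result.alternatives
    out: list[tuple[tuple[str, str], tuple[float, float]]] = []
    n = len(alts)
    for t in range(len(betas) - 1):
        lo, hi = ranks[t], ranks[t + 1]
        for a in range(n):
            for b in range(a + 1, n):
                if np.sign(lo[a] - lo[b]) != np.sign(hi[a] - hi[b]):
                    out.append(((alts[a], alts[b]), (betas[t], betas[t + 1])))
    return out
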