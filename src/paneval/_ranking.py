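"""Shared ranking helper: descending ordinal ranks with a stable tie rule."""

from __future__ import annotations

import numpy as np


def rank_descending(values) -> np.ndarray:
    """Rank values descending: rank 1 = largest.

    Exact ties are broken deterministically by input (first-occurrence)
    order, so the result is always a permutation of 1..n.
    """
    v = np.asarray(values, dtype=float)
    order = np.argsort(-v, kind="stable")
    ranks = np.empty(v.size, dtype=int)
    ranks[order] = np.arange(1, v.size + 1)
    return ranks
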