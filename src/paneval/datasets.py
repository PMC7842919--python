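"""Bundled example panel: Chinese maternal health care indicators, 2004-2018.

Six yearbook indicators per year: X1 = maternal mortality (deaths per
100,000, cost direction), X2-X6 = registration, system management, prenatal
check-up, postpartum visit and hospital delivery rates (percent, benefit
direction).  Available in two forms:

``raw``
    The values as published, X1 in deaths per 100,000.
``cotrended``
    X1 replaced by its difference co-trend ``100000 - X1`` so every column is
    larger-is-better.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .panel import BENEFIT, COST, IndicatorPanel, IndicatorSchema

CHINA_MCH_YEARS = tuple(str(y) for y in range(2004, 2019))
CHINA_MCH_INDICATORS = ("X1", "X2", "X3", "X4", "X5", "X6")
CHINA_MCH_COST_REFERENCE = 100000.0

# rows: years 2004..2018; columns: X1 (per 100,000), X2..X6 (%)
CHINA_MCH_RAW = np.array(
    [
        [48.3, 88.3, 76.4, 89.7, 85.9, 82.8],
        [47.7, 88.5, 76.7, 89.8, 86.0, 85.9],
        [41.1, 88.2, 76.5, 89.7, 85.7, 88.4],
        [36.6, 89.3, 77.3, 90.9, 86.7, 91.7],
        [34.2, 89.3, 78.1, 91.0, 87.0, 94.5],
        [31.9, 90.9, 80.9, 92.2, 88.7, 96.3],
        [30.0, 92.9, 84.1, 94.1, 90.8, 97.8],
        [26.1, 93.8, 85.2, 93.7, 91.0, 98.7],
        [24.5, 94.8, 87.6, 95.0, 92.6, 99.2],
        [23.2, 95.7, 89.5, 95.6, 93.5, 99.5],
        [21.7, 95.8, 90.0, 96.2, 93.9, 99.6],
        [20.1, 96.4, 91.5, 96.5, 94.5, 99.7],
        [19.9, 96.6, 91.6, 96.6, 94.6, 99.8],
        [19.6, 96.6, 89.6, 96.5, 94.0, 99.9],
        [18.3, 92.5, 89.9, 96.6, 93.8, 99.9],
    ]
)


def fixture_china_mch(form: str = "raw") -> IndicatorPanel:
    """Return the bundled 15x6 panel.

    Parameters
    ----------
    form:
        ``"raw"`` for the published values (X1 a cost indicator) or
        ``"cotrended"`` for the difference co-trended matrix (X1 already
        converted to ``100000 - X1``, all columns benefit direction).
    """
    if form == "raw":
        schema = (
            IndicatorSchema(
                direction=COST,
                cost_reference=CHINA_MCH_COST_REFERENCE,
                cotrend_method="reciprocal",
            ),
        ) + tuple(IndicatorSchema(direction=BENEFIT) for _ in range(5))
        values = CHINA_MCH_RAW
    elif form == "cotrended":
        schema = tuple(IndicatorSchema(direction=BENEFIT) for _ in range(6))
        values = CHINA_MCH_RAW.copy()
        values[:, 0] = CHINA_MCH_COST_REFERENCE - values[:, 0]
    else:
        raise ValidationError(f"unknown fixture form {form!r}; use 'raw' or 'cotrended'")
    return IndicatorPanel(
        alternatives=CHINA_MCH_YEARS,
        indicators=CHINA_MCH_INDICATORS,
        values=values,
        schema=schema,
    )
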