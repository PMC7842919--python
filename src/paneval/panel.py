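"""Indicator panel data model and CSV/schema I/O.

A panel is a rectangular alternatives (rows) x indicators (columns) table of
real values.  Each indicator carries a direction flag: ``benefit`` (larger is
better) or ``cost`` (smaller is better).  Cost indicators may additionally
carry a reference value used by the difference co-trend and a co-trend method
selection (see :mod:`paneval.normalize`).

The value matrix travels as a plain CSV file (header row of indicator labels,
first column of alternative labels); the per-indicator metadata lives in a
sidecar YAML/JSON schema so the matrix file stays a standard table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

BENEFIT = "benefit"
COST = "cost"
_DIRECTIONS = (BENEFIT, COST)


@dataclass(frozen=True)
class IndicatorSchema:
    """Per-indicator metadata.

    Parameters
    ----------
    direction:
        ``"benefit"`` or ``"cost"``.
    cost_reference:
        Reference value for the difference co-trend of a cost indicator
        (must exceed every observed value).  ``None`` when unused.
    cotrend_method:
        ``"reciprocal"`` (default) or ``"difference"``; only meaningful for
        cost indicators.
    """

    direction: str
    cost_reference: float | None = None
    cotrend_method: str = "reciprocal"

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValidationError(
                f"unknown direction {self.direction!r}; expected one of {_DIRECTIONS}"
            )
        if self.cotrend_method not in ("reciprocal", "difference"):
            raise ValidationError(
                f"unknown cotrend method {self.cotrend_method!r}"
            )
        if self.cotrend_method == "difference" and self.direction == COST and self.cost_reference is None:
            raise ValidationError("difference co-trend requires a cost_reference")


@dataclass(frozen=True)
class IndicatorPanel:
    """Validated alternatives x indicators value matrix with metadata."""

    alternatives: tuple[str, ...]
    indicators: tuple[str, ...]
    values: np.ndarray
    schema: tuple[IndicatorSchema, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "alternatives", tuple(str(a) for a in self.alternatives))
        object.__setattr__(self, "indicators", tuple(str(c) for c in self.indicators))
        object.__setattr__(self, "schema", tuple(self.schema))
        n, m = len(self.alternatives), len(self.indicators)
        if n < 2:
            raise ValidationError(f"need at least 2 alternatives, got {n}")
        if m < 1:
            raise ValidationError("need at least 1 indicator")
        if values.shape != (n, m):
            raise ValidationError(
                f"value matrix shape {values.shape} does not match "
                f"{n} alternatives x {m} indicators"
            )
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"missing or non-finite value at row {self.alternatives[i]!r}, "
                f"column {self.indicators[j]!r}"
            )
        if len(set(self.alternatives)) != n:
            raise ValidationError("duplicate alternative labels")
        if len(set(self.indicators)) != m:
            raise ValidationError("duplicate indicator labels")
        if len(self.schema) != m:
            raise ValidationError(
                f"schema has {len(self.schema)} entries for {m} indicators"
            )
        for j, spec in enumerate(self.schema):
            ref = spec.cost_reference
            if ref is not None and ref <= values[:, j].max():
                raise ValidationError(
                    f"cost_reference {ref} for {self.indicators[j]!r} does not "
                    f"exceed the column maximum {values[:, j].max()}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def directions(self) -> tuple[str, ...]:
        return tuple(s.direction for s in self.schema)

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.indicators.index(label)]

    def value(self, alternative: str, indicator: str) -> float:
        i = self.alternatives.index(str(alternative))
        j = self.indicators.index(indicator)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.alternatives), columns=list(self.indicators)
        )

    def with_schema(self, schema: Sequence[IndicatorSchema]) -> "IndicatorPanel":
        return replace(self, schema=tuple(schema))


# -- schema (sidecar config) ---------------------------------------------------


def schema_from_mapping(
    mapping: Mapping[str, Mapping[str, object]], indicators: Sequence[str]
) -> tuple[IndicatorSchema, ...]:
    """Build an ordered schema tuple from a label -> properties mapping."""
    out = []
    for label in indicators:
        if label not in mapping:
            raise ValidationError(f"schema missing entry for indicator {label!r}")
        entry = dict(mapping[label])
        unknown = set(entry) - {"direction", "cost_reference", "cotrend_method"}
        if unknown:
            raise ValidationError(f"unknown schema keys for {label!r}: {sorted(unknown)}")
        ref = entry.get("cost_reference")
        out.append(
            IndicatorSchema(
                direction=str(entry.get("direction", "")),
                cost_reference=None if ref is None else float(ref),
                cotrend_method=str(entry.get("cotrend_method", "reciprocal")),
            )
        )
    return tuple(out)


def read_schema(path: str | Path) -> dict[str, dict[str, object]]:
    """Read a YAML or JSON indicator schema file into a plain mapping."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"schema file {path} must contain a mapping")
    return data


def write_schema(mapping: Mapping[str, Mapping[str, object]], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(mapping, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(dict(mapping), sort_keys=False), encoding="utf-8")


# -- panel I/O -----------------------------------------------------------------


def read_panel(
    path: str | Path, schema: Mapping[str, Mapping[str, object]] | str | Path
) -> IndicatorPanel:
    """Read a panel from a CSV file plus a direction/reference schema.

    The CSV must be comma-separated UTF-8 with a header row of indicator
    labels and a first column of alternative labels.  ``schema`` is either a
    mapping (indicator label -> {direction, cost_reference, cotrend_method})
    or the path of a YAML/JSON file containing one.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"panel file not found: {path}")
    if isinstance(schema, (str, Path)):
        schema = read_schema(schema)

    with path.open(encoding="utf-8") as fh:
        rows = [line.rstrip("\n").split(",") for line in fh if line.strip()]
    if len(rows) < 2:
        raise ValidationError(f"{path}: need a header row and at least one data row")
    header = rows[0]
    width = len(header)
    indicators = [h.strip() for h in header[1:]]
    alternatives: list[str] = []
    values = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValidationError(f"{path}: ragged row at line {lineno}")
        label = row[0].strip()
        parsed = []
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if not cell:
                raise ValidationError(
                    f"{path}: blank cell at line {lineno}, column {indicators[j]!r}"
                )
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                    f"column {indicators[j]!r}"
                ) from None
        alternatives.append(label)
        values.append(parsed)

    return IndicatorPanel(
        alternatives=tuple(alternatives),
        indicators=tuple(indicators),
        values=np.array(values, dtype=float),
        schema=schema_from_mapping(schema, indicators),
    )


def write_panel(panel: IndicatorPanel, path: str | Path) -> None:
    """Write the value matrix as CSV (full precision, round-trip safe)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("alternative," + ",".join(panel.indicators) + "\n")
        for label, row in zip(panel.alternatives, panel.values):
            fh.write(label + "," + ",".join(repr(float(v)) for v in row) + "\n")


def schema_as_mapping(panel: IndicatorPanel) -> dict[str, dict[str, object]]:
    """Export a panel's schema in the sidecar-file mapping form."""
    out: dict[str, dict[str, object]] = {}
    for label, spec in zip(panel.indicators, panel.schema):
        entry: dict[str, object] = {"direction": spec.direction}
        if spec.cost_reference is not None:
            entry["cost_reference"] = spec.cost_reference
        if spec.direction == COST:
            entry["cotrend_method"] = spec.cotrend_method
        out[label] = entry
    return out
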