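"""CSV/YAML/JSON readers and writers with location-aware validation."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ann import NormalizationSpec
from .desirability import DesirabilityGoal
from .doe import FactorSpec
from .errors import ValidationError
from .rsm import QuadraticModel

__all__ = [
    "load_table",
    "save_model_json",
    "load_model_json",
    "load_factors_yaml",
    "load_goals_yaml",
    "load_normalization_yaml",
]


def load_table(
    path: str | Path,
    schema: dict[str, tuple[float, float] | None],
) -> pd.DataFrame:
    """Read a headered CSV and validate it against a column schema.

    ``schema`` maps each required column to an optional (low, high) bound
    pair for its numeric values.  Errors name the offending column and the
    1-based data row.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except Exception as exc:  # parse failure, missing file
        raise ValidationError(f"{path}: cannot read CSV ({exc})") from exc
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    out = pd.DataFrame(index=raw.index)
    for col, bounds in schema.items():
        if bounds is _TEXT:
            out[col] = raw[col]
            continue
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.index[numeric.isna() & raw[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value {raw[col][bad[0]]!r} in column "
                f"{col!r} at row {bad[0] + 1}"
            )
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0]) + 1
            raise ValidationError(f"{path}: empty cell in column {col!r} at row {row}")
        if bounds is not None:
            lo, hi = bounds
            viol = numeric.index[(numeric < lo) | (numeric > hi)]
            if len(viol):
                raise ValidationError(
                    f"{path}: value {numeric[viol[0]]} in column {col!r} at row "
                    f"{viol[0] + 1} outside [{lo}, {hi}]"
                )
        out[col] = numeric.to_numpy(dtype=float)
    return out


class _Text:
    """Sentinel marking a schema column as free text."""


_TEXT = _Text()
TEXT = _TEXT


def load_design_csv(
    path: str | Path,
    factors: tuple[FactorSpec, ...],
    response_cols: list[str] | None = None,
):
    """Design table from CSV (natural units); coded levels are derived.

    Columns beyond ``run`` and the factor names are treated as responses
    unless ``response_cols`` narrows them explicitly.
    """
    from .doe import DesignMatrix, map_units

    names = [f.name for f in factors]
    header = pd.read_csv(path, nrows=0).columns
    if response_cols is None:
        response_cols = [c for c in header if c not in names and c != "run"]
    schema: dict = {f.name: (f.low, f.high) for f in factors}
    schema.update({c: None for c in response_cols})
    table = load_table(path, schema)
    natural = table[names]
    design = DesignMatrix(
        factors=tuple(factors),
        coded=natural.copy(),  # placeholder until map_units fills coded levels
        natural=natural,
        run_order=np.arange(len(table)),
    )
    design = map_units(design, "natural->coded")
    if response_cols:
        design = design.with_responses(table[response_cols])
    return design


def save_model_json(model: QuadraticModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def load_model_json(path: str | Path) -> QuadraticModel:
    try:
        return QuadraticModel.from_dict(json.loads(Path(path).read_text()))
    except (KeyError, json.JSONDecodeError) as exc:
        raise ValidationError(f"{path}: malformed model file ({exc})") from exc


def load_factors_yaml(path: str | Path) -> tuple[FactorSpec, ...]:
    """Factor specs from YAML: a list of {name, low, high} mappings."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, list):
        raise ValidationError(f"{path}: expected a YAML list of factors")
    factors = []
    for i, item in enumerate(doc):
        try:
            factors.append(FactorSpec(str(item["name"]), float(item["low"]), float(item["high"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: bad factor entry #{i + 1} ({exc})") from exc
    return tuple(factors)


def load_goals_yaml(path: str | Path) -> list[DesirabilityGoal]:
    """Desirability goals from YAML: list of {variable, kind, low, high, weight}."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, list):
        raise ValidationError(f"{path}: expected a YAML list of goals")
    goals = []
    for i, item in enumerate(doc):
        try:
            goals.append(
                DesirabilityGoal(
                    variable=str(item["variable"]),
                    kind=str(item["kind"]),
                    low=float(item["low"]),
                    high=float(item["high"]),
                    weight=float(item.get("weight", 3.0)),
                    target=(float(item["target"]) if "target" in item else None),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: bad goal entry #{i + 1} ({exc})") from exc
    return goals


def load_normalization_yaml(path: str | Path) -> NormalizationSpec:
    """Normalization ranges from YAML: mapping name -> [low, high]."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: expected a YAML mapping of attribute ranges")
    try:
        return NormalizationSpec({str(k): (float(v[0]), float(v[1])) for k, v in doc.items()})
    except (TypeError, ValueError, IndexError) as exc:
        raise ValidationError(f"{path}: bad normalization entry ({exc})") from exc


def dump_json(obj, path: str | Path) -> None:
    """Write a JSON report, converting numpy scalars/arrays transparently."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
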