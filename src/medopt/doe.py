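"""Box-Behnken designs and coded/natural unit conversion.

A three-level Box-Behnken design (BBD) for k factors places, for every one
of the C(k,2) factor pairs, the four (+/-1, +/-1) combinations with all
remaining factors at their center level, plus a block of center replicates.
Coded levels are exactly {-1, 0, +1}; natural levels are concentrations in
g/L obtained by the affine map

    x_nat = center + x_coded * (high - low) / 2 .

The canonical (pre-randomization) run order is deterministic: factor pairs
in lexicographic index order, within each pair (-1,-1), (+1,-1), (-1,+1),
(+1,+1), center runs last.  Randomized run order is a seeded permutation of
the canonical order; a seed is mandatory so every design is reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import RangeError, UnsupportedDesignError, ValidationError

__all__ = ["FactorSpec", "DesignMatrix", "generate_bbd", "map_units"]


@dataclass(frozen=True)
class FactorSpec:
    """One medium component varied in the design.

    Parameters
    ----------
    name : str
        Factor label, unique within a design (e.g. ``"cellulose"``).
    low, high : float
        Natural-unit bounds in g/L mapped to coded -1 and +1.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def to_natural(self, coded: np.ndarray) -> np.ndarray:
        return self.center + np.asarray(coded, dtype=float) * self.half_range

    def to_coded(self, natural: np.ndarray) -> np.ndarray:
        return (np.asarray(natural, dtype=float) - self.center) / self.half_range


@dataclass
class DesignMatrix:
    """Runs x factors in coded and natural units, with optional responses.

    ``coded`` and ``natural`` are kept consistent under the per-factor affine
    level map; ``run_order`` records the permutation applied to the canonical
    ordering (``run_order[i]`` is the canonical index of stored row ``i``).
    """

    factors: tuple[FactorSpec, ...]
    coded: pd.DataFrame
    natural: pd.DataFrame
    run_order: np.ndarray
    responses: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate factor names: {names}")
        if list(self.coded.columns) != names or list(self.natural.columns) != names:
            raise ValidationError("design columns must match factor names in order")

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return {f.name: (f.low, f.high) for f in self.factors}

    def with_responses(self, responses: pd.DataFrame) -> "DesignMatrix":
        if len(responses) != self.n_runs:
            raise ValidationError(
                f"responses have {len(responses)} rows, design has {self.n_runs}"
            )
        return replace(self, responses=responses.reset_index(drop=True))

    def to_frame(self, units: str = "natural") -> pd.DataFrame:
        """Tidy table: run index, factor columns, response columns."""
        base = self.natural if units == "natural" else self.coded
        out = base.copy()
        out.insert(0, "run", np.arange(1, self.n_runs + 1))
        if self.responses is not None:
            for col in self.responses.columns:
                out[col] = self.responses[col].to_numpy()
        return out


def _canonical_bbd(k: int, center_replicates: int) -> np.ndarray:
    rows: list[list[float]] = []
    for i, j in itertools.combinations(range(k), 2):
        for a, b in ((-1, -1), (+1, -1), (-1, +1), (+1, +1)):
            row = [0.0] * k
            row[i], row[j] = float(a), float(b)
            rows.append(row)
    rows.extend([[0.0] * k for _ in range(center_replicates)])
    return np.asarray(rows)


def generate_bbd(
    factors: list[FactorSpec] | tuple[FactorSpec, ...],
    center_replicates: int,
    seed: int,
) -> DesignMatrix:
    """Generate a three-level Box-Behnken design with randomized run order.

    Total runs = 4*C(k,2) + center_replicates (27 for k=4 with 3 center
    replicates).  The run order is a permutation drawn from
    ``numpy.random.default_rng(seed)``; passing a seed is mandatory.
    """
    factors = tuple(factors)
    k = len(factors)
    if k < 3:
        raise UnsupportedDesignError(
            f"Box-Behnken designs need at least 3 factors, got {k}"
        )
    if center_replicates < 1:
        raise ValidationError(
            f"center_replicates must be >= 1, got {center_replicates}"
        )
    if seed is None:
        raise ValidationError("a seed is required; unseeded designs are not reproducible")

    coded = _canonical_bbd(k, center_replicates)
    perm = np.random.default_rng(seed).permutation(len(coded))
    coded = coded[perm]
    names = [f.name for f in factors]
    coded_df = pd.DataFrame(coded, columns=names)
    natural_df = pd.DataFrame(
        {f.name: f.to_natural(coded[:, i]) for i, f in enumerate(factors)}
    )[names]
    return DesignMatrix(factors=factors, coded=coded_df, natural=natural_df, run_order=perm)


def map_units(design: DesignMatrix, direction: str) -> DesignMatrix:
    """Recompute one representation from the other via the affine level map.

    ``direction`` is ``"coded->natural"`` or ``"natural->coded"``.  Source
    values must lie within the factor bounds ([-1, 1] coded, [low, high]
    natural); violations raise :class:`RangeError` naming factor and run.
    """
    if direction not in ("coded->natural", "natural->coded"):
        raise ValidationError(f"unknown direction {direction!r}")
    tol = 1e-9
    if direction == "coded->natural":
        src = design.coded
        for f in design.factors:
            bad = np.flatnonzero(np.abs(src[f.name].to_numpy()) > 1 + tol)
            if bad.size:
                raise RangeError(
                    f"coded value for factor {f.name!r} out of [-1, 1] at run {bad[0] + 1}"
                )
        natural = pd.DataFrame(
            {f.name: f.to_natural(src[f.name].to_numpy()) for f in design.factors}
        )[design.factor_names]
        return replace(design, natural=natural)
    src = design.natural
    for f in design.factors:
        vals = src[f.name].to_numpy()
        bad = np.flatnonzero((vals < f.low - tol) | (vals > f.high + tol))
        if bad.size:
            raise RangeError(
                f"natural value for factor {f.name!r} out of "
                f"[{f.low}, {f.high}] g/L at run {bad[0] + 1}"
            )
    coded = pd.DataFrame(
        {f.name: f.to_coded(src[f.name].to_numpy()) for f in design.factors}
    )[design.factor_names]
    return replace(design, coded=coded)
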