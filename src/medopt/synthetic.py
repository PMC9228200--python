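"""Synthetic experiment generator.

The study's run-level responses were never published, so every pipeline
stage is exercised on emulated data: Box-Behnken responses drawn from a
known quadratic surface (defaulting to the study's fitted coefficient sets)
plus Gaussian replicate noise, and screening replicate sets constructed to
hit prescribed group means and within-group sums of squares exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doe import DesignMatrix
from .errors import ValidationError
from .rsm import QuadraticModel, predict_response

__all__ = [
    "SyntheticExperimentSpec",
    "simulate_bbd_responses",
    "make_screening_groups",
]


@dataclass(frozen=True)
class SyntheticExperimentSpec:
    """Ground truth for a simulated Box-Behnken experiment.

    ``models`` maps response name -> true quadratic surface (natural units);
    replicate noise is i.i.d. Gaussian with standard deviation ``noise_sd``
    mm.  The default noise of 0.5 mm puts the fitted R^2 of a 27-run design
    in the mid-0.9s, the regime of the study being emulated.
    """

    design: DesignMatrix
    models: dict[str, QuadraticModel]
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for name, mdl in self.models.items():
            if tuple(mdl.factor_names) != tuple(self.design.factor_names):
                raise ValidationError(
                    f"model {name!r} factors {mdl.factor_names} do not match "
                    f"design factors {tuple(self.design.factor_names)}"
                )


def simulate_bbd_responses(spec: SyntheticExperimentSpec) -> DesignMatrix:
    """Evaluate the true surfaces at every run and add seeded Gaussian noise.

    With ``noise_sd = 0`` the responses equal the exact surface values.  One
    child generator per response keeps columns independent and the whole
    table reproducible from the single seed.
    """
    X = spec.design.natural
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for name, mdl in spec.models.items():
        clean = np.array(
            [
                predict_response(mdl, row, extrapolate=True)
                for row in X[list(mdl.factor_names)].to_numpy()
            ]
        )
        noise = rng.normal(0.0, spec.noise_sd, size=len(clean)) if spec.noise_sd else 0.0
        cols[name] = clean + noise
    return spec.design.with_responses(pd.DataFrame(cols))


def make_screening_groups(
    means: dict[str, float],
    within_ss_total: float,
    n_per_group: int,
) -> pd.DataFrame:
    """Long-format replicate table with exact means and exact within-group SS.

    Each group of n replicates alternates m + d and m - d, so the group mean
    is exactly m and each group contributes n * d^2 to the within-group sum
    of squares; d = sqrt(within_ss_total / (n_groups * n)) splits the
    requested total evenly across groups.  n must be even so the +/- pairs
    cancel.
    """
    if n_per_group % 2 != 0 or n_per_group < 2:
        raise ValidationError(
            "n_per_group must be even and >= 2 (replicates are built as +/- pairs)"
        )
    if within_ss_total < 0:
        raise ValidationError("within_ss_total must be >= 0")
    if not means:
        raise ValidationError("need at least one group mean")
    d = float(np.sqrt(within_ss_total / (len(means) * n_per_group)))
    rows = []
    for label, m in means.items():
        for r in range(n_per_group):
            rows.append((label, m + d if r % 2 == 0 else m - d))
    return pd.DataFrame(rows, columns=["source", "zone_mm"])
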