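"""Reference study constants for the Bacillus sp. BioSolAfla medium study.

Published summary statistics of the cultivation-medium optimization study
this package re-analyzes: the Box-Behnken factor ranges, the two fitted
quadratic surfaces for the inhibition-zone diameter against the aflatoxigenic
isolates *Aspergillus flavus* SA2BSS and PA2DSS (natural g/L units), the
screening group means with their ANOVA error terms, and the attribute
normalization ranges used in the neural-network branch.  The run-level raw
responses were never deposited, so these summaries are the anchor for the
synthetic-data generator and the validation suite.
"""

from __future__ import annotations

from .ann import NormalizationSpec
from .doe import FactorSpec
from .rsm import QuadraticModel

__all__ = [
    "FACTORS",
    "SA2BSS_MODEL",
    "PA2DSS_MODEL",
    "REFERENCE_MODELS",
    "CARBON_SCREEN",
    "NITROGEN_SCREEN",
    "NORMALIZATION",
    "OPTIMAL_MEDIUM",
]

# Design factors: three-level ranges in g/L.
FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("cellulose", 5.0, 35.0),
    FactorSpec("urea", 0.0, 5.0),
    FactorSpec("ammonium_sulfate", 0.0, 5.0),
    FactorSpec("dipotassium_phosphate", 0.5, 4.5),
)

_NAMES = tuple(f.name for f in FACTORS)


def _model(response: str, b0, lin, inter, quad) -> QuadraticModel:
    return QuadraticModel(
        factor_names=_NAMES,
        intercept=b0,
        linear=dict(zip(_NAMES, lin)),
        interaction={
            (_NAMES[0], _NAMES[1]): inter[0],
            (_NAMES[0], _NAMES[2]): inter[1],
            (_NAMES[0], _NAMES[3]): inter[2],
            (_NAMES[1], _NAMES[2]): inter[3],
            (_NAMES[1], _NAMES[3]): inter[4],
            (_NAMES[2], _NAMES[3]): inter[5],
        },
        quadratic=dict(zip(_NAMES, quad)),
        units_mode="natural",
        response_name=response,
        factors=FACTORS,
    )


# Inhibition-zone diameter (mm) surfaces in natural units, coefficient order
# b0; b1..b4; b12, b13, b14, b23, b24, b34; b11..b44
# (1 cellulose, 2 urea, 3 ammonium sulfate, 4 dipotassium phosphate).
SA2BSS_MODEL = _model(
    "SA2BSS",
    38.98960,
    (-0.33876, -1.49165, -1.59720, -3.70852),
    (0.00000, 0.00667, 0.05278, 0.25333, -0.01667, 0.15000),
    (0.00512, 0.17111, 0.03111, 0.52779),
)

PA2DSS_MODEL = _model(
    "PA2DSS",
    24.21942,
    (-0.10015, 0.48611, 1.52500, 0.23958),
    (-0.02000, 0.00222, 0.02500, -0.12000, 0.05000, -0.25000),
    (0.00414, 0.00222, -0.10444, -0.01736),
)

REFERENCE_MODELS: dict[str, QuadraticModel] = {
    "SA2BSS": SA2BSS_MODEL,
    "PA2DSS": PA2DSS_MODEL,
}

# OFAT screening summaries: group means (mm), the within-group (error) sum
# of squares, error df, and replicates per group, from the published one-way
# ANOVA of each selection step.
CARBON_SCREEN = {
    "means": {
        "starch": 22.33333,
        "lactose": 23.83333,
        "glucose": 23.83333,
        "maltose": 24.16667,
        "glycerol": 24.33333,
        "fructose": 26.16667,
        "cellulose": 26.33333,
    },
    "within_ss": 43.33333,
    "df_error": 35,
    "ms_error": 1.24,
    "n_per_group": 6,
}

NITROGEN_SCREEN = {
    "means": {
        "peptone": 25.00000,
        "yeast_extract": 25.00000,
        "tryptone": 28.16667,
        "l_glutamic_acid": 30.33333,
        "urea": 31.50000,
    },
    "within_ss": 71.66667,
    "df_error": 25,
    "ms_error": 2.87,
    "n_per_group": 6,
}

# Attribute normalization ranges for the neural-network branch (original
# units; all scaled to [0, 1]).
NORMALIZATION = NormalizationSpec(
    {
        "cellulose": (0.0, 50.0),
        "urea": (0.0, 10.0),
        "ammonium_sulfate": (0.0, 10.0),
        "dipotassium_phosphate": (0.0, 10.0),
        "SA2BSS": (10.0, 40.0),
        "PA2DSS": (10.0, 40.0),
    }
)

# Optimized medium composition (g/L) reported by the study's desirability run.
OPTIMAL_MEDIUM = {
    "cellulose": 5.0,
    "urea": 0.0,
    "ammonium_sulfate": 3.77,
    "dipotassium_phosphate": 0.5,
}
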