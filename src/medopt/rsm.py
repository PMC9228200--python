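"""Second-degree polynomial response-surface modelling.

The response surface is the full quadratic polynomial in the k factors,

    Y = b0 + sum_i b_i X_i + sum_{i<j} b_ij X_i X_j + sum_i b_ii X_i^2 ,

fitted by ordinary least squares on the expanded basis.  For k = 4 the model
has 15 coefficients, so a 27-run Box-Behnken design leaves 12 residual
degrees of freedom.  Fits are performed in natural units (g/L) by default;
coded-unit fits give different coefficient values but identical predictions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .doe import DesignMatrix, FactorSpec
from .errors import RangeError, SingularFitError, ValidationError

__all__ = [
    "QuadraticModel",
    "FitDiagnostics",
    "fit_quadratic",
    "predict_response",
    "response_gradient",
    "model_anova",
    "adjusted_r2",
    "surface_slice",
    "compare_models",
    "quadratic_basis",
]


@dataclass(frozen=True)
class QuadraticModel:
    """Full quadratic response-surface model for k factors.

    Coefficients are keyed by factor name: ``linear[name]``,
    ``interaction[(name_i, name_j)]`` with i < j in factor order, and
    ``quadratic[name]``.  ``units_mode`` records whether the coefficients
    apply to natural (g/L) or coded (-1..+1) factor values and is enforced
    at prediction time.  ``factors`` (optional) carries the design bounds
    used for extrapolation checks.
    """

    factor_names: tuple[str, ...]
    intercept: float
    linear: dict[str, float]
    interaction: dict[tuple[str, str], float]
    quadratic: dict[str, float]
    units_mode: str = "natural"
    response_name: str = "response"
    factors: tuple[FactorSpec, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        k = len(self.factor_names)
        if self.units_mode not in ("natural", "coded"):
            raise ValidationError(f"units_mode must be natural|coded, got {self.units_mode!r}")
        expected_pairs = set(itertools.combinations(self.factor_names, 2))
        if (
            set(self.linear) != set(self.factor_names)
            or set(self.quadratic) != set(self.factor_names)
            or set(self.interaction) != expected_pairs
        ):
            raise ValidationError(
                f"quadratic model for k={k} needs 1 + {k} + {k * (k - 1) // 2} + {k} coefficients"
            )

    @property
    def n_terms(self) -> int:
        k = len(self.factor_names)
        return 1 + 2 * k + k * (k - 1) // 2

    def coefficient_vector(self) -> np.ndarray:
        """Coefficients in basis order: 1, X_i, X_i X_j (i<j), X_i^2."""
        vals = [self.intercept]
        vals += [self.linear[n] for n in self.factor_names]
        vals += [self.interaction[p] for p in itertools.combinations(self.factor_names, 2)]
        vals += [self.quadratic[n] for n in self.factor_names]
        return np.asarray(vals)

    def to_dict(self) -> dict:
        """JSON-ready representation (b0, b1.., b12.., b11.. naming)."""
        idx = {n: i + 1 for i, n in enumerate(self.factor_names)}
        coefs: dict[str, float] = {"b0": self.intercept}
        for n in self.factor_names:
            coefs[f"b{idx[n]}"] = self.linear[n]
        for a, b in itertools.combinations(self.factor_names, 2):
            coefs[f"b{idx[a]}{idx[b]}"] = self.interaction[(a, b)]
        for n in self.factor_names:
            coefs[f"b{idx[n]}{idx[n]}"] = self.quadratic[n]
        out = {
            "factor_names": list(self.factor_names),
            "units_mode": self.units_mode,
            "response_name": self.response_name,
            "coefficients": coefs,
        }
        if self.factors is not None:
            out["factor_bounds"] = {f.name: [f.low, f.high] for f in self.factors}
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticModel":
        names = tuple(d["factor_names"])
        idx = {n: i + 1 for i, n in enumerate(names)}
        c = d["coefficients"]
        factors = None
        if d.get("factor_bounds"):
            factors = tuple(
                FactorSpec(n, *d["factor_bounds"][n]) for n in names if n in d["factor_bounds"]
            )
        return cls(
            factor_names=names,
            intercept=float(c["b0"]),
            linear={n: float(c[f"b{idx[n]}"]) for n in names},
            interaction={
                (a, b): float(c[f"b{idx[a]}{idx[b]}"])
                for a, b in itertools.combinations(names, 2)
            },
            quadratic={n: float(c[f"b{idx[n]}{idx[n]}"]) for n in names},
            units_mode=d.get("units_mode", "natural"),
            response_name=d.get("response_name", "response"),
            factors=factors,
        )


@dataclass(frozen=True)
class FitDiagnostics:
    """Inference summary of a least-squares quadratic fit."""

    terms: tuple[str, ...]
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r2: float
    adj_r2: float
    f_value: float
    f_pvalue: float
    ss_model: float
    ss_residual: float
    df_model: int
    df_residual: int

    def coefficient_table(self, model: QuadraticModel) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coefficient": model.coefficient_vector(),
                "std_error": self.std_errors,
                "t": self.t_values,
                "p": np.round(self.p_values, 6),
            }
        )


def quadratic_basis(X: pd.DataFrame, names: list[str] | tuple[str, ...]) -> pd.DataFrame:
    """Expand factor columns into the quadratic design basis.

    Column order: const, each X_i, each X_i:X_j (i<j), each X_i^2.
    """
    cols: dict[str, np.ndarray] = {"const": np.ones(len(X))}
    for n in names:
        cols[n] = X[n].to_numpy(dtype=float)
    for a, b in itertools.combinations(names, 2):
        cols[f"{a}:{b}"] = cols[a] * cols[b]
    for n in names:
        cols[f"{n}^2"] = cols[n] ** 2
    return pd.DataFrame(cols)


def fit_quadratic(
    design: DesignMatrix,
    response: str,
    units_mode: str = "natural",
) -> tuple[QuadraticModel, FitDiagnostics]:
    """Fit the full quadratic surface to one response column by OLS.

    Coefficient p-values are two-sided t tests on the residual degrees of
    freedom; R-squared and the model F test are computed on corrected totals.
    """
    if design.responses is None or response not in design.responses.columns:
        raise ValidationError(f"design has no response column {response!r}")
    names = design.factor_names
    k = len(names)
    n_terms = 1 + 2 * k + k * (k - 1) // 2
    n = design.n_runs
    if n <= n_terms:
        raise ValidationError(
            f"insufficient data: {n} runs for {n_terms} terms leaves no residual df"
        )
    X = design.natural if units_mode == "natural" else design.coded
    basis = quadratic_basis(X, names)
    rank = np.linalg.matrix_rank(basis.to_numpy())
    if rank < n_terms:
        _, R = np.linalg.qr(basis.to_numpy())
        aliased = [basis.columns[i] for i in range(n_terms) if abs(R[i, i]) < 1e-8]
        raise SingularFitError(f"rank-deficient quadratic basis; aliased terms: {aliased}")

    y = design.responses[response].to_numpy(dtype=float)
    res = sm.OLS(y, basis).fit()

    beta = res.params.to_numpy()
    model = QuadraticModel(
        factor_names=tuple(names),
        intercept=float(beta[0]),
        linear={nm: float(beta[1 + i]) for i, nm in enumerate(names)},
        interaction={
            pair: float(beta[1 + k + j])
            for j, pair in enumerate(itertools.combinations(names, 2))
        },
        quadratic={nm: float(beta[1 + k + k * (k - 1) // 2 + i]) for i, nm in enumerate(names)},
        units_mode=units_mode,
        response_name=response,
        factors=design.factors,
    )
    diag = FitDiagnostics(
        terms=tuple(basis.columns),
        std_errors=res.bse.to_numpy(),
        t_values=res.tvalues.to_numpy(),
        p_values=res.pvalues.to_numpy(),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_value=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        ss_model=float(res.ess),
        ss_residual=float(res.ssr),
        df_model=int(res.df_model),
        df_residual=int(res.df_resid),
    )
    return model, diag


def _point_array(model: QuadraticModel, point) -> np.ndarray:
    if isinstance(point, dict):
        arr = np.asarray([point[n] for n in model.factor_names], dtype=float)
    else:
        arr = np.asarray(point, dtype=float)
    if arr.shape[-1] != len(model.factor_names):
        raise ValidationError(
            f"point has {arr.shape[-1]} coordinates, model has {len(model.factor_names)} factors"
        )
    return arr


def predict_response(
    model: QuadraticModel,
    point,
    extrapolate: bool = False,
) -> float:
    """Evaluate the quadratic polynomial at one factor combination.

    ``point`` is a sequence or name->value mapping in the model's own units.
    When the model carries factor bounds and ``extrapolate`` is False, points
    outside the design box raise :class:`RangeError` — the fitted surface is
    only trusted inside the experimental region.
    """
    x = _point_array(model, point)
    if model.factors is not None and not extrapolate and model.units_mode == "natural":
        tol = 1e-9
        for f, v in zip(model.factors, x):
            if v < f.low - tol or v > f.high + tol:
                raise RangeError(
                    f"factor {f.name!r} = {v} g/L outside design range "
                    f"[{f.low}, {f.high}]; pass extrapolate=True to override"
                )
    names = model.factor_names
    val = model.intercept
    for i, n in enumerate(names):
        val += model.linear[n] * x[i]
        val += model.quadratic[n] * x[i] ** 2
    for (a, b), c in model.interaction.items():
        val += c * x[names.index(a)] * x[names.index(b)]
    return float(val)


def response_gradient(model: QuadraticModel, point) -> dict[str, float]:
    """Analytic gradient dY/dX_i of the quadratic surface at a point."""
    x = _point_array(model, point)
    names = model.factor_names
    grad = {}
    for i, n in enumerate(names):
        g = model.linear[n] + 2.0 * model.quadratic[n] * x[i]
        for (a, b), c in model.interaction.items():
            if a == n:
                g += c * x[names.index(b)]
            elif b == n:
                g += c * x[names.index(a)]
        grad[n] = float(g)
    return grad


def model_anova(
    model: QuadraticModel,
    design: DesignMatrix,
    response: str,
    uncorrected: bool = False,
) -> "pd.DataFrame":
    """ANOVA partition of the fitted surface (corrected totals by default).

    SS_model + SS_residual = SS_total; F = MS_model / MS_residual.  The
    ``uncorrected`` diagnostic mode partitions raw (not mean-centered) sums
    of squares, in which case the model row absorbs the grand mean.
    """
    from .screening import AnovaTable  # local import to avoid cycle

    if design.responses is None or response not in design.responses.columns:
        raise ValidationError(f"design has no response column {response!r}")
    y = design.responses[response].to_numpy(dtype=float)
    X = design.natural if model.units_mode == "natural" else design.coded
    yhat = quadratic_basis(X, design.factor_names).to_numpy() @ model.coefficient_vector()

    ss_res = float(np.sum((y - yhat) ** 2))
    if uncorrected:
        ss_tot = float(np.sum(y**2))
    else:
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_mod = ss_tot - ss_res
    df_mod = model.n_terms - (0 if uncorrected else 1)
    df_res = len(y) - model.n_terms
    ms_mod = ss_mod / df_mod
    if ss_res <= 1e-300:
        f_val, p_val = float("inf"), 0.0
    else:
        ms_res = ss_res / df_res
        f_val = ms_mod / ms_res
        p_val = float(stats.f.sf(f_val, df_mod, df_res))
    rows = [
        ("model", ss_mod, df_mod, ms_mod, f_val, p_val),
        ("residual", ss_res, df_res, ss_res / df_res, np.nan, np.nan),
        ("total", ss_tot, df_mod + df_res, np.nan, np.nan, np.nan),
    ]
    table = AnovaTable(
        pd.DataFrame(rows, columns=["source", "SS", "DF", "MS", "F", "p"])
    )
    table.r2 = ss_mod / ss_tot if ss_tot > 0 else np.nan
    return table


def adjusted_r2(r2: float, n_runs: int, n_terms: int) -> float:
    """Size-penalized R^2: 1 - (1 - R^2)(n - 1)/(n - p), p counting the intercept."""
    if n_runs <= n_terms:
        raise ValidationError(
            f"adjusted R^2 undefined for n_runs={n_runs} <= n_terms={n_terms}"
        )
    return 1.0 - (1.0 - r2) * (n_runs - 1) / (n_runs - n_terms)


def surface_slice(
    model: QuadraticModel,
    vary: tuple[str, str],
    fixed: dict[str, float] | None = None,
    grid: int = 30,
) -> pd.DataFrame:
    """Predicted response over a 2-D grid, remaining factors held fixed.

    ``fixed`` defaults to the design center of each non-varied factor (the
    model must then carry factor bounds).  Returns a tidy frame with columns
    for the two varied factors and the prediction.
    """
    f1, f2 = vary
    if f1 == f2:
        raise ValidationError("vary factors must be distinct")
    for f in vary:
        if f not in model.factor_names:
            raise KeyError(f"unknown factor {f!r}")
    if model.factors is None:
        raise ValidationError("model carries no factor bounds; cannot build a slice grid")
    spec = {f.name: f for f in model.factors}
    fixed = dict(fixed or {})
    for n in model.factor_names:
        if n not in vary and n not in fixed:
            fixed[n] = spec[n].center
    for n in fixed:
        if n not in model.factor_names:
            raise KeyError(f"unknown factor {n!r}")

    g1 = np.linspace(spec[f1].low, spec[f1].high, grid)
    g2 = np.linspace(spec[f2].low, spec[f2].high, grid)
    rows = []
    for v2 in g2:
        for v1 in g1:
            point = dict(fixed)
            point[f1], point[f2] = float(v1), float(v2)
            rows.append(
                (v1, v2, predict_response(model, point, extrapolate=True))
            )
    return pd.DataFrame(rows, columns=[f1, f2, model.response_name])


def compare_models(entries: list[tuple[str, float]]) -> pd.DataFrame:
    """Rank candidate models by adjusted R^2, flagging the best.

    Ties are all flagged, preserving input label order among tied entries.
    """
    if not entries:
        raise ValidationError("compare_models needs at least one entry")
    df = pd.DataFrame(entries, columns=["model", "adj_r2"])
    df = df.sort_values("adj_r2", ascending=False, kind="stable").reset_index(drop=True)
    best = df["adj_r2"].max()
    df["selected"] = np.isclose(df["adj_r2"], best, rtol=0.0, atol=1e-12)
    return df
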