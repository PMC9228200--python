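"""Derringer-Suich desirability scoring and medium optimization.

Each optimization goal maps a factor concentration or a predicted response
onto a desirability d in [0, 1]:

    minimize:  d = ((high - value) / (high - low)) ** weight, clipped
    maximize:  d = ((value - low) / (high - low)) ** weight, clipped
    in_range:  d = 1 inside [low, high], 0 outside
    target:    two-sided ramp peaking at the target, weight on both arms

The overall desirability D is the geometric mean of all per-goal values
(zero if any goal scores zero), maximized over the factor box by seeded
multi-start bounded Nelder-Mead search starting from every box corner, the
center, and random interior points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import ValidationError
from .rsm import QuadraticModel, predict_response

__all__ = [
    "DesirabilityGoal",
    "OptimizationResult",
    "desirability_score",
    "overall_desirability",
    "optimize_medium",
]

_KINDS = ("minimize", "maximize", "in_range", "target")


@dataclass(frozen=True)
class DesirabilityGoal:
    """One optimization goal on a factor or a response.

    ``low`` and ``high`` bound the ramp; for ``target`` goals ``target``
    locates the peak.  ``weight`` is the exponent on the linear ramp, in the
    conventional 1-5 range (3 everywhere in the study being re-analyzed).
    """

    variable: str
    kind: str
    low: float
    high: float
    weight: float = 3.0
    target: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"goal kind must be one of {_KINDS}, got {self.kind!r}")
        if not self.low < self.high:
            raise ValidationError(f"goal {self.variable!r}: low must be < high")
        if not 1.0 <= self.weight <= 5.0:
            raise ValidationError(f"goal {self.variable!r}: weight must be in [1, 5]")
        if self.kind == "target":
            if self.target is None or not self.low < self.target < self.high:
                raise ValidationError(
                    f"goal {self.variable!r}: target must lie strictly inside (low, high)"
                )


def desirability_score(goal: DesirabilityGoal, value: float) -> float:
    """Per-goal desirability of one value; always in [0, 1]."""
    if not np.isfinite(value):
        raise ValidationError(f"non-finite value for goal {goal.variable!r}")
    lo, hi, w = goal.low, goal.high, goal.weight
    span = hi - lo
    if goal.kind == "minimize":
        d = (hi - value) / span
    elif goal.kind == "maximize":
        d = (value - lo) / span
    elif goal.kind == "in_range":
        return 1.0 if lo <= value <= hi else 0.0
    else:  # target
        t = goal.target
        d = (value - lo) / (t - lo) if value <= t else (hi - value) / (hi - t)
    return float(np.clip(d, 0.0, 1.0) ** w)


def overall_desirability(ds) -> float:
    """Geometric mean of per-goal desirabilities; zero if any is zero."""
    ds = np.asarray(list(ds), dtype=float)
    if ds.size == 0:
        raise ValidationError("need at least one desirability value")
    if np.any((ds < 0) | (ds > 1)):
        raise ValidationError("desirabilities must lie in [0, 1]")
    if np.any(ds == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(ds))))


@dataclass(frozen=True)
class OptimizationResult:
    """Optimal medium composition with its desirability breakdown."""

    point: dict[str, float]
    predicted: dict[str, float]
    per_goal: dict[str, float]
    overall: float
    n_starts: int
    n_evaluations: int = field(compare=False, default=0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.overall <= 1.0:
            raise ValidationError("overall desirability outside [0, 1]")


def _corners_and_center(bounds: list[tuple[float, float]]) -> np.ndarray:
    k = len(bounds)
    pts = [
        [bounds[i][(m >> i) & 1] for i in range(k)] for m in range(2**k)
    ]
    pts.append([0.5 * (lo + hi) for lo, hi in bounds])
    return np.asarray(pts, dtype=float)


def optimize_medium(
    models: dict[str, QuadraticModel],
    goals: list[DesirabilityGoal],
    bounds: dict[str, tuple[float, float]],
    seed: int,
    n_starts: int = 64,
) -> OptimizationResult:
    """Maximize overall desirability D over the factor box.

    Multi-start bounded Nelder-Mead: deterministic starts at all box corners
    and the center, topped up with seeded uniform interior starts to
    ``n_starts`` total.  Near-ties in D (within 1e-9) are resolved toward the
    lower total nutrient mass.  If D = 0 everywhere the least-bad point is
    returned with a warning.
    """
    if not goals:
        raise ValidationError("need at least one goal")
    factor_names = list(bounds)
    for g in goals:
        if g.variable not in factor_names and g.variable not in models:
            raise ValidationError(
                f"goal variable {g.variable!r} is neither a factor nor a model name"
            )
    box = [tuple(map(float, bounds[n])) for n in factor_names]
    evals = 0

    def score(x: np.ndarray) -> tuple[float, dict, dict]:
        point = dict(zip(factor_names, (float(v) for v in x)))
        preds = {
            name: predict_response(mdl, [point[n] for n in mdl.factor_names], extrapolate=True)
            for name, mdl in models.items()
        }
        per_goal = {}
        for g in goals:
            value = point[g.variable] if g.variable in point else preds[g.variable]
            per_goal[g.variable] = desirability_score(g, value)
        return overall_desirability(per_goal.values()), per_goal, preds

    def neg_d(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        return -score(np.clip(x, [b[0] for b in box], [b[1] for b in box]))[0]

    rng = np.random.default_rng(seed)
    starts = _corners_and_center(box)
    extra = max(0, n_starts - len(starts))
    if extra:
        rand = rng.uniform(
            [b[0] for b in box], [b[1] for b in box], size=(extra, len(box))
        )
        starts = np.vstack([starts, rand])

    candidates: list[tuple[float, np.ndarray]] = []
    for x0 in starts:
        res = optimize.minimize(
            neg_d,
            x0,
            method="Nelder-Mead",
            bounds=box,
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
        )
        x = np.clip(res.x, [b[0] for b in box], [b[1] for b in box])
        candidates.append((-res.fun, x))

    best_d = max(d for d, _ in candidates)
    near = [x for d, x in candidates if d >= best_d - 1e-9]
    x_best = min(near, key=lambda x: float(np.sum(x)))
    d_best, per_goal, preds = score(x_best)
    if d_best == 0.0:
        warnings.warn(
            "overall desirability is zero everywhere searched; returning the "
            "least-bad point",
            stacklevel=2,
        )
    return OptimizationResult(
        point=dict(zip(factor_names, (float(v) for v in x_best))),
        predicted=preds,
        per_goal=per_goal,
        overall=d_best,
        n_starts=len(starts),
        n_evaluations=evals,
    )
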