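"""Desirability optimization of the medium composition.

Maximizes the geometric-mean desirability over the design box with the
study's goal set: minimize cellulose and urea (cheap medium), keep the two
salts in range, maximize both predicted inhibition zones (10-40 mm ramps),
all weights 3.  The optimum lands on the corner cellulose 5.00, urea 0.00,
dipotassium phosphate 0.50 g/L, with ammonium sulfate interior — matching
the published optimized medium.
"""

import json
from pathlib import Path

from medopt import default_goals, optimize_medium, response_gradient
from medopt import reference as ref
from medopt.io import load_model_json

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2026


def main() -> None:
    models = {
        resp: load_model_json(RESULTS / f"model_{resp}.json")
        for resp in ("SA2BSS", "PA2DSS")
    }
    goals = default_goals(ref.FACTORS, {"SA2BSS": (10.0, 40.0), "PA2DSS": (10.0, 40.0)})
    bounds = {f.name: (f.low, f.high) for f in ref.FACTORS}
    result = optimize_medium(models, goals, bounds, seed=SEED)

    point = [result.point[f.name] for f in ref.FACTORS]
    certificates = {
        resp: response_gradient(m, point) for resp, m in models.items()
    }
    blob = {
        "optimal_medium_g_per_L": result.point,
        "predicted_responses_mm": result.predicted,
        "per_goal_desirability": result.per_goal,
        "overall_desirability": result.overall,
        "gradient_at_optimum": certificates,
    }
    (RESULTS / "optimum.json").write_text(json.dumps(blob, indent=2) + "\n")
    print("optimal medium (g/L):", {k: round(v, 2) for k, v in result.point.items()})
    print("predicted responses (mm):", {k: round(v, 2) for k, v in result.predicted.items()})
    print(f"overall desirability D = {result.overall:.3f}")
    down = all(
        certificates[r][f] < 0
        for r in certificates
        for f in ("cellulose", "urea", "dipotassium_phosphate")
    )
    print("corner certificate (all slopes negative at optimum):", down)


if __name__ == "__main__":
    main()
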