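"""Build the 27-run Box-Behnken design and simulate its responses.

The four factors (cellulose 5-35, urea 0-5, ammonium sulfate 0-5,
dipotassium phosphate 0.5-4.5 g/L) at three levels give 24 edge-midpoint
runs plus 3 center replicates.  Responses for both fungal isolates are drawn
from the reference quadratic surfaces with 0.5 mm Gaussian replicate noise —
the stand-in for the study's unpublished run-level measurements.  Also emits
the all-attribute correlation screen.
"""

from pathlib import Path

from medopt import (
    SyntheticExperimentSpec,
    correlation_screen,
    generate_bbd,
    simulate_bbd_responses,
)
from medopt import reference as ref

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2026


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    design = generate_bbd(ref.FACTORS, center_replicates=3, seed=SEED)
    design = simulate_bbd_responses(
        SyntheticExperimentSpec(
            design=design,
            models=dict(ref.REFERENCE_MODELS),
            noise_sd=0.5,
            seed=SEED,
        )
    )
    design.to_frame("natural").to_csv(RESULTS / "design_with_responses.csv", index=False)
    corr = correlation_screen(design)
    corr.to_csv(RESULTS / "correlation_screen.csv")
    print(f"{design.n_runs}-run design written; responses {list(design.responses.columns)}")
    print("strongest factor-response correlations:")
    for resp in design.responses.columns:
        sub = corr.loc[design.factor_names, resp].abs().sort_values(ascending=False)
        print(f"  {resp}: {sub.index[0]} (|r|={sub.iloc[0]:.2f})")


if __name__ == "__main__":
    main()
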