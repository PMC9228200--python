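"""Compare the RSM and ANN model families by adjusted R-squared.

The quadratic surfaces' adjusted R^2 comes from the OLS fit; the neural
predictors' from their validation R^2 on the 27 original points, penalized
for the four inputs plus intercept.  The family with the higher adjusted
coefficient carries forward into the optimization stage.
"""

from pathlib import Path

import pandas as pd

from medopt import compare_models

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ann = pd.read_csv(RESULTS / "ann_metrics.csv")
    entries = []
    for resp in ann["isolate"]:
        coef = pd.read_csv(RESULTS / f"coefficients_{resp}.csv")
        anova = pd.read_csv(RESULTS / f"model_anova_{resp}.csv")
        ss = dict(zip(anova["source"], anova["SS"]))
        r2 = ss["model"] / ss["total"]
        from medopt import adjusted_r2

        entries.append((f"RSM {resp}", adjusted_r2(r2, 27, len(coef))))
        row = ann[ann["isolate"] == resp].iloc[0]
        entries.append((f"ANN {resp}", row["adj_r2"]))
    table = compare_models(entries)
    table.to_csv(RESULTS / "model_comparison.csv", index=False)
    print(table.to_string(index=False))
    winner = table.iloc[0]["model"]
    print(f"\nselected family: {winner.split()[0]}")


if __name__ == "__main__":
    main()
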