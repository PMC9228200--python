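"""Autoencoder augmentation and MLP prediction for each isolate.

Normalizes the 27 simulated runs to [0, 1], trains one autoencoder per
isolate (4 factors + that isolate's response), decodes 10,000 embedding
samples drawn uniformly from [-1, 2.5], trains the three-hidden-layer
perceptron on the augmented rows only, and validates on the 27 original
points, which never enter training — the augmentation-success check.
"""

from pathlib import Path

import pandas as pd

from medopt import reference as ref
from medopt.ann import (
    AugmentationConfig,
    AutoencoderConfig,
    PredictorConfig,
    augment,
    rescale,
    train_autoencoder,
    train_predictor,
    validate_on_original,
)
from medopt.io import load_design_csv
from medopt.rsm import adjusted_r2

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2026


def main() -> None:
    design = load_design_csv(RESULTS / "design_with_responses.csv", ref.FACTORS)
    rows = []
    for i, resp in enumerate(design.responses.columns):
        cols = list(design.factor_names) + [resp]
        original = rescale(design.to_frame("natural")[cols], ref.NORMALIZATION, "to_unit")
        _, decoder, ae_report = train_autoencoder(
            original.to_numpy(), AutoencoderConfig(seed=SEED + i)
        )
        augmented = augment(
            decoder, AugmentationConfig(seed=SEED + 10 + i), columns=cols
        )
        # full 10,000-row table is regenerable from the seed; keep a preview
        augmented.data.head(200).to_csv(RESULTS / f"augmented_{resp}_preview.csv", index=False)
        net, train_report = train_predictor(
            augmented.data[design.factor_names],
            augmented.data[resp],
            PredictorConfig(seed=SEED + 20 + i),
        )
        val_mse, val_r2 = validate_on_original(
            net, original[design.factor_names], original[resp]
        )
        rows.append(
            {
                "isolate": resp,
                "ae_reconstruction_mse": ae_report["reconstruction_mse"],
                "ae_reconstruction_r2": ae_report["reconstruction_r2"],
                "mlp_train_mse": train_report["train_mse"],
                "validation_mse": val_mse,
                "validation_r2": val_r2,
                "adj_r2": adjusted_r2(val_r2, design.n_runs, len(design.factor_names) + 1),
            }
        )
        print(
            f"{resp}: AE recon R2={ae_report['reconstruction_r2']:.3f}, "
            f"validation R2 on 27 originals={val_r2:.3f}"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "ann_metrics.csv", index=False)


if __name__ == "__main__":
    main()
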