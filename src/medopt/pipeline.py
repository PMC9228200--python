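"""End-to-end pipeline: screening -> RSM -> ANN -> comparison -> optimization.

``run_pipeline`` wires the individual stages together the way the medium
study proceeds: screening statistics (when screening data are supplied), a
quadratic surface fit per response, the autoencoder-augmentation/MLP branch,
model comparison by adjusted R^2, and desirability optimization with the
winning family.  The report embeds every seed and configuration, so a rerun
from the embedded config reproduces all deterministic numbers.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .ann import (
    AugmentationConfig,
    AutoencoderConfig,
    NormalizationSpec,
    PredictorConfig,
    augment,
    rescale,
    train_autoencoder,
    train_predictor,
    validate_on_original,
)
from .desirability import DesirabilityGoal, optimize_medium
from .doe import DesignMatrix, FactorSpec, generate_bbd
from .errors import MedoptError
from .io import dump_json
from .rsm import QuadraticModel, adjusted_r2, compare_models, fit_quadratic, model_anova
from .screening import duncan_mrt, one_way_anova
from .synthetic import SyntheticExperimentSpec, make_screening_groups, simulate_bbd_responses

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, seeds included.

    With no measured design supplied the run simulates a Box-Behnken
    experiment from the reference surfaces at ``noise_sd`` mm of replicate
    noise — the stand-in for the study's unpublished raw responses.
    """

    seed: int = 0
    factors: tuple[FactorSpec, ...] = reference.FACTORS
    center_replicates: int = 3
    design: DesignMatrix | None = None  # measured design with responses, if any
    truth_models: dict[str, QuadraticModel] = field(
        default_factory=lambda: dict(reference.REFERENCE_MODELS)
    )
    noise_sd: float = 0.5
    screening_data: dict[str, pd.DataFrame] | None = None
    screening_alpha: float = 0.05
    normalization: NormalizationSpec = reference.NORMALIZATION
    ann_enabled: bool = True
    autoencoder: AutoencoderConfig = AutoencoderConfig()
    augmentation: AugmentationConfig = AugmentationConfig()
    predictor: PredictorConfig = PredictorConfig()
    goals: list[DesirabilityGoal] | None = None  # default built from data at run time
    response_bounds: str = "observed"  # or "normalization"
    output_dir: str | Path | None = None


def default_goals(
    factors: tuple[FactorSpec, ...],
    response_bounds: dict[str, tuple[float, float]],
    weight: float = 3.0,
) -> list[DesirabilityGoal]:
    """The study's goal set: cheap medium, both responses maximal.

    Minimize the carbon and organic nitrogen sources, keep the two salts in
    range, maximize both inhibition-zone responses; every goal carries the
    same weight (3 by default).
    """
    by_name = {f.name: f for f in factors}
    goals = [
        DesirabilityGoal("cellulose", "minimize", by_name["cellulose"].low, by_name["cellulose"].high, weight),
        DesirabilityGoal("urea", "minimize", by_name["urea"].low, by_name["urea"].high, weight),
        DesirabilityGoal(
            "ammonium_sulfate", "in_range", by_name["ammonium_sulfate"].low, by_name["ammonium_sulfate"].high, weight
        ),
        DesirabilityGoal(
            "dipotassium_phosphate",
            "in_range",
            by_name["dipotassium_phosphate"].low,
            by_name["dipotassium_phosphate"].high,
            weight,
        ),
    ]
    for name, (lo, hi) in response_bounds.items():
        goals.append(DesirabilityGoal(name, "maximize", lo, hi, weight))
    return goals


def _seed_for(base: int, stage: str) -> int:
    # zlib.crc32 is stable across processes, unlike builtin str hashing
    return int(np.random.default_rng([base, zlib.crc32(stage.encode())]).integers(2**31))


def _ann_branch(cfg: PipelineConfig, design: DesignMatrix, response: str) -> dict:
    """One isolate's augmentation + prediction arm on normalized attributes."""
    cols = list(design.factor_names) + [response]
    original = rescale(design.to_frame("natural")[cols], cfg.normalization, "to_unit")
    ae_cfg = AutoencoderConfig(
        **{**asdict(cfg.autoencoder), "seed": _seed_for(cfg.seed, f"ae-{response}")}
    )
    _, decoder, ae_report = train_autoencoder(original.to_numpy(), ae_cfg)
    aug_cfg = AugmentationConfig(
        n_samples=cfg.augmentation.n_samples,
        interval=cfg.augmentation.interval,
        seed=_seed_for(cfg.seed, f"aug-{response}"),
    )
    augmented = augment(decoder, aug_cfg, columns=cols)
    pred_cfg = PredictorConfig(
        **{**asdict(cfg.predictor), "seed": _seed_for(cfg.seed, f"mlp-{response}")}
    )
    net, train_report = train_predictor(
        augmented.data[design.factor_names], augmented.data[response], pred_cfg
    )
    val_mse, val_r2 = validate_on_original(
        net, original[design.factor_names], original[response]
    )
    # adjusted R^2 analog on the 27 validation rows, one slope per input + intercept
    p_eff = len(design.factor_names) + 1
    return {
        "response": response,
        "autoencoder": {
            "reconstruction_mse": ae_report["reconstruction_mse"],
            "reconstruction_r2": ae_report["reconstruction_r2"],
            "epochs": ae_report["epochs"],
            "seed": ae_cfg.seed,
        },
        "augmentation": {"n_samples": len(augmented.data), "interval": aug_cfg.interval, "seed": aug_cfg.seed},
        "predictor": {
            "hidden_layers": list(pred_cfg.hidden_layers),
            "train_mse": train_report["train_mse"],
            "validation_mse": val_mse,
            "validation_r2": val_r2,
            "adj_r2": adjusted_r2(val_r2, design.n_runs, p_eff),
            "seed": pred_cfg.seed,
        },
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every configured stage and return the JSON-ready report.

    Any stage failure is re-raised annotated with the stage name.  When
    ``cfg.output_dir`` is set the report is also written to
    ``<output_dir>/report.json``.
    """
    report: dict = {
        "provenance": {
            "seed": cfg.seed,
            "noise_sd": cfg.noise_sd,
            "factors": {f.name: [f.low, f.high] for f in cfg.factors},
            "ann_enabled": cfg.ann_enabled,
        }
    }
    stage = "screening"
    try:
        if cfg.screening_data:
            scr = {}
            for label, table in cfg.screening_data.items():
                aov = one_way_anova(table)
                means = table.groupby("source")["zone_mm"].mean()
                sizes = table.groupby("source")["zone_mm"].size()
                duncan = duncan_mrt(
                    means.to_dict(),
                    int(sizes.iloc[0]),
                    float(aov.row("within")["MS"]),
                    int(aov.row("within")["DF"]),
                    cfg.screening_alpha,
                )
                scr[label] = {
                    "anova": aov.frame.to_dict(orient="records"),
                    "duncan": duncan.to_frame().to_dict(orient="records"),
                }
            report["screening"] = scr

        stage = "design"
        design = cfg.design
        if design is None:
            design = generate_bbd(cfg.factors, cfg.center_replicates, _seed_for(cfg.seed, "design"))
            design = simulate_bbd_responses(
                SyntheticExperimentSpec(
                    design=design,
                    models=cfg.truth_models,
                    noise_sd=cfg.noise_sd,
                    seed=_seed_for(cfg.seed, "responses"),
                )
            )
            report["provenance"]["design"] = "simulated"
        responses = list(design.responses.columns)
        report["design"] = {"n_runs": design.n_runs, "responses": responses}

        stage = "rsm"
        rsm_models: dict[str, QuadraticModel] = {}
        rsm_report = {}
        for resp in responses:
            model, diag = fit_quadratic(design, resp)
            aov = model_anova(model, design, resp)
            rsm_models[resp] = model
            rsm_report[resp] = {
                "coefficients": model.to_dict()["coefficients"],
                "r2": diag.r2,
                "adj_r2": diag.adj_r2,
                "f_value": diag.f_value,
                "f_pvalue": diag.f_pvalue,
                "df_residual": diag.df_residual,
                "anova": aov.frame.to_dict(orient="records"),
            }
        report["rsm"] = rsm_report

        stage = "ann"
        if cfg.ann_enabled:
            report["ann"] = {resp: _ann_branch(cfg, design, resp) for resp in responses}

        stage = "comparison"
        if cfg.ann_enabled:
            entries = []
            for resp in responses:
                entries.append((f"RSM {resp}", rsm_report[resp]["adj_r2"]))
                entries.append((f"ANN {resp}", report["ann"][resp]["predictor"]["adj_r2"]))
            comparison = compare_models(entries)
            rsm_mean = np.mean([rsm_report[r]["adj_r2"] for r in responses])
            ann_mean = np.mean(
                [report["ann"][r]["predictor"]["adj_r2"] for r in responses]
            )
            selected_family = "RSM" if rsm_mean >= ann_mean else "ANN"
            report["comparison"] = {
                "table": comparison.to_dict(orient="records"),
                "selected_family": selected_family,
            }
        else:
            selected_family = "RSM"

        stage = "optimization"
        goals = cfg.goals
        if goals is None:
            if cfg.response_bounds == "normalization":
                rb = {r: cfg.normalization.ranges[r] for r in responses}
            else:
                rb = {
                    r: (
                        float(design.responses[r].min()),
                        float(design.responses[r].max()),
                    )
                    for r in responses
                }
            goals = default_goals(cfg.factors, rb)
        # optimization always runs on the quadratic surfaces; the ANN branch
        # informs the comparison but is not an evaluable closed-form model set
        result = optimize_medium(
            rsm_models,
            goals,
            {f.name: (f.low, f.high) for f in cfg.factors},
            seed=_seed_for(cfg.seed, "optimize"),
        )
        report["optimization"] = {
            "point": result.point,
            "predicted": result.predicted,
            "per_goal": result.per_goal,
            "overall_desirability": result.overall,
            "model_family_used": selected_family,
        }
    except MedoptError as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        dump_json(report, out / "report.json")
    return report


def default_screening_data() -> dict[str, pd.DataFrame]:
    """Reference-anchored screening fixtures (carbon and nitrogen steps)."""
    return {
        "carbon": make_screening_groups(
            reference.CARBON_SCREEN["means"],
            reference.CARBON_SCREEN["within_ss"],
            reference.CARBON_SCREEN["n_per_group"],
        ),
        "nitrogen": make_screening_groups(
            reference.NITROGEN_SCREEN["means"],
            reference.NITROGEN_SCREEN["within_ss"],
            reference.NITROGEN_SCREEN["n_per_group"],
        ),
    }
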