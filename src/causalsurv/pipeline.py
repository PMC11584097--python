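"""End-to-end experiment orchestration.

One configuration drives: simulate (or load) source and target cohorts,
train the discrete-latent autoencoder (A), the latent estimator (B), and
the hazard model (C); estimate the latent shift from target features,
fine-tune on estimator-derived latents, and evaluate causal and baseline
models per site.  Ablation configurations mirror the modular design:
``drop_shift_adjustment`` removes only the prevalence-ratio rescaling,
``latent_only`` scores from the discrete latent alone, ``features_only``
from the features alone.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autoencoder import (EncoderState, assign_latents, save_encoder,
                          train_autoencoder)
from .baselines import baseline_predict, fit_baseline
from .estimator import (EstimatorState, ShiftEstimate, estimate_shift,
                        save_estimator, train_estimator)
from .evaluation import BootstrapSpec, site_report
from .io_tables import (CohortTable, TrainingConfig, read_cohort,
                        write_report)
from .riskmodel import (RiskModelBundle, finetune_on_estimated_latents,
                        predict, save_risk_model, train_risk_model)
from .synthetic import (SimulationConfig, simulate_domain, write_simulation)

ABLATIONS = ("full", "drop_shift_adjustment", "latent_only", "features_only")

__all__ = [
    "ABLATIONS",
    "ExperimentConfig",
    "FittedPipeline",
    "stage_seed",
    "fit_pipeline",
    "run_experiment",
    "run_ablation_suite",
]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the experiment seed."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class ExperimentConfig:
    training: TrainingConfig = field(default_factory=TrainingConfig)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    simulation: SimulationConfig | None = None
    cohort_P_path: str | None = None
    cohort_Q_path: str | None = None
    ablation: str = "full"
    include_baselines: bool = True
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        has_files = self.cohort_P_path is not None
        if has_files == (self.simulation is not None):
            raise ValueError(
                "provide exactly one input source: files or simulation")
        if has_files and self.cohort_Q_path is None:
            raise ValueError("cohort_Q_path required with cohort_P_path")


@dataclass
class FittedPipeline:
    """Trained components of one pipeline variant."""

    ablation: str
    training: TrainingConfig
    ae: EncoderState | None = None
    estimator: EstimatorState | None = None
    bundle: RiskModelBundle | None = None
    shift: ShiftEstimate | None = None

    def risk_scores(self, cohort: CohortTable,
                    adjusted: bool | None = None) -> np.ndarray:
        """Per-patient risk scores under this variant's inference rule."""
        if self.ablation in ("latent_only",):
            latents = assign_latents(self.ae, cohort)
            out = predict(self.bundle, cohort, "unadjusted",
                          latents_onehot=latents.onehot)
            return out["risk"]
        if self.ablation == "features_only":
            out = predict(self.bundle, cohort, "unadjusted")
            return out["risk"]
        if adjusted is None:
            adjusted = self.ablation == "full"
        mode = "adjusted" if adjusted else "unadjusted"
        # the model adjusts by the predicted latent shift of the data it
        # scores: the evaluation cohort is treated as one target domain
        shift = None
        if adjusted:
            from .estimator import estimate_shift
            shift = estimate_shift(self.estimator, cohort.features,
                                   prevalence_mode=self.training.prevalence_mode)
        out = predict(self.bundle, cohort, mode, estimator=self.estimator,
                      shift=shift,
                      normalize=self.training.normalize_adjusted_posterior)
        return out["risk"]


def fit_pipeline(cohort_P: CohortTable, cohort_Q: CohortTable,
                 config: TrainingConfig, ablation: str = "full",
                 ae: EncoderState | None = None,
                 estimator: EstimatorState | None = None
                 ) -> FittedPipeline:
    """Train one pipeline variant on a source cohort with internal splits.

    Pre-trained ``ae``/``estimator`` components may be passed in so that
    ablation variants share byte-identical upstream checkpoints.
    """
    if ablation not in ABLATIONS:
        raise ValueError(f"ablation must be one of {ABLATIONS}")
    train = cohort_P.subset("internal-train")
    val = cohort_P.subset("internal-val")
    if len(val) == 0:
        val = None

    if ablation == "features_only":
        cfg = dataclasses.replace(config,
                                  seed=stage_seed(config.seed, "risk"))
        bundle = train_risk_model(train, None, cfg, val_cohort=val,
                                  feature_input=True, latent_input=False)
        return FittedPipeline(ablation, config, bundle=bundle)

    if ae is None:
        cfg = dataclasses.replace(config, seed=stage_seed(config.seed, "ae"))
        ae = train_autoencoder(train, cfg, val_cohort=val)
    latents = assign_latents(ae, train)
    val_latents = assign_latents(ae, val) if val is not None else None

    if ablation == "latent_only":
        cfg = dataclasses.replace(config,
                                  seed=stage_seed(config.seed, "risk"))
        bundle = train_risk_model(
            train, latents.onehot, cfg, val_cohort=val,
            val_latents_onehot=(val_latents.onehot
                                if val_latents is not None else None),
            feature_input=False, latent_input=True)
        return FittedPipeline(ablation, config, ae=ae, bundle=bundle)

    if estimator is None:
        cfg = dataclasses.replace(config,
                                  seed=stage_seed(config.seed, "estimator"))
        estimator = train_estimator(train, ae, cfg, val_cohort=val)
    shift = estimate_shift(estimator, cohort_Q.features,
                           prevalence_mode=config.prevalence_mode)

    cfg = dataclasses.replace(config, seed=stage_seed(config.seed, "risk"))
    bundle = train_risk_model(
        train, latents.onehot, cfg, val_cohort=val,
        val_latents_onehot=(val_latents.onehot
                            if val_latents is not None else None))
    cfg_ft = dataclasses.replace(config,
                                 seed=stage_seed(config.seed, "finetune"))
    bundle = finetune_on_estimated_latents(bundle, train, estimator, cfg_ft,
                                           val_cohort=val)
    bundle.shift = shift
    return FittedPipeline(ablation, config, ae=ae, estimator=estimator,
                          bundle=bundle, shift=shift)


def _load_cohorts(config: ExperimentConfig
                  ) -> tuple[CohortTable, CohortTable]:
    if config.simulation is not None:
        sim = dataclasses.replace(
            config.simulation, seed=stage_seed(config.seed, "simulate"))
        return (simulate_domain(sim, "P").table,
                simulate_domain(sim, "Q").table)
    return (read_cohort(config.cohort_P_path),
            read_cohort(config.cohort_Q_path))


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the staged pipeline; returns the run directory.

    Writes checkpoints, the shift estimate, per-domain evaluation
    reports, and the resolved configuration.  Fully deterministic for a
    fixed configuration and seed.
    """
    if config.outdir is not None:
        outdir = Path(config.outdir)
    else:
        outdir = Path("runs") / f"run_seed{config.seed}_{config.ablation}"
    outdir.mkdir(parents=True, exist_ok=True)

    cohort_P, cohort_Q = _load_cohorts(config)
    if config.simulation is not None:
        sim = dataclasses.replace(
            config.simulation, seed=stage_seed(config.seed, "simulate"))
        write_simulation(sim, outdir / "sim")

    training = dataclasses.replace(config.training, seed=config.seed)
    fitted = fit_pipeline(cohort_P, cohort_Q, training, config.ablation)

    if fitted.ae is not None:
        save_encoder(fitted.ae, outdir / "ae.json")
    if fitted.estimator is not None:
        save_estimator(fitted.estimator, outdir / "estimator.json")
    if fitted.bundle is not None:
        save_risk_model(fitted.bundle, outdir / "risk.json")
    if fitted.shift is not None:
        with open(outdir / "shift.json", "w") as fh:
            json.dump(fitted.shift.to_dict(), fh, indent=2)

    internal_test = cohort_P.subset("internal-test")
    external_test = cohort_Q

    model_scores_int = {config.ablation: fitted.risk_scores(internal_test)}
    model_scores_ext = {config.ablation: fitted.risk_scores(external_test)}
    if config.ablation == "full":
        model_scores_int["unadjusted"] = fitted.risk_scores(
            internal_test, adjusted=False)
        model_scores_ext["unadjusted"] = fitted.risk_scores(
            external_test, adjusted=False)
    if config.include_baselines:
        train = cohort_P.subset("internal-train")
        val = cohort_P.subset("internal-val")
        cox_cfg = dataclasses.replace(
            training, seed=stage_seed(config.seed, "baseline"))
        cox = fit_baseline("cox_linear", train, cox_cfg)
        deeps = fit_baseline("deepsurv_mlp", train, cox_cfg,
                             val_cohort=val if len(val) else None)
        for name, model in (("cox", cox), ("deepsurv", deeps)):
            model_scores_int[name] = baseline_predict(model, internal_test)
            model_scores_ext[name] = baseline_predict(model, external_test)

    spec = dataclasses.replace(
        config.bootstrap, seed=stage_seed(config.seed, "bootstrap"))
    horizon = training.horizon_months
    for tag, cohort, scores in (
            ("internal", internal_test, model_scores_int),
            ("external", external_test, model_scores_ext)):
        reports = site_report(scores, cohort, spec, horizon=horizon,
                              seed=config.seed)
        combined = {name: r.to_dict() for name, r in reports.items()}
        with open(outdir / f"report_{tag}.json", "w") as fh:
            json.dump(combined, fh, indent=2, sort_keys=True)
        for name, r in reports.items():
            write_report(r, outdir / f"report_{tag}_{name}.json")

    resolved = {
        "seed": config.seed,
        "ablation": config.ablation,
        "training": training.to_dict(),
        "bootstrap": dataclasses.asdict(spec),
        "simulation": (config.simulation.to_dict()
                       if config.simulation is not None else None),
        "cohort_P_path": config.cohort_P_path,
        "cohort_Q_path": config.cohort_Q_path,
    }
    with open(outdir / "resolved_config.json", "w") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True)
    return outdir


def run_ablation_suite(config: ExperimentConfig):
    """Full model plus the three ablations on shared data and seeds.

    Returns a DataFrame with one row per configuration and internal /
    external C-index columns with bootstrap CIs; upstream components
    (autoencoder, estimator) are trained once and shared.
    """
    import pandas as pd

    cohort_P, cohort_Q = _load_cohorts(config)
    training = dataclasses.replace(config.training, seed=config.seed)

    full = fit_pipeline(cohort_P, cohort_Q, training, "full")
    variants = {
        "full": full,
        "drop_shift_adjustment": FittedPipeline(
            "drop_shift_adjustment", training, ae=full.ae,
            estimator=full.estimator, bundle=full.bundle, shift=full.shift),
        "latent_only": fit_pipeline(cohort_P, cohort_Q, training,
                                    "latent_only", ae=full.ae),
        "features_only": fit_pipeline(cohort_P, cohort_Q, training,
                                      "features_only"),
    }

    internal_test = cohort_P.subset("internal-test")
    spec = dataclasses.replace(
        config.bootstrap, seed=stage_seed(config.seed, "bootstrap"))
    horizon = training.horizon_months
    rows = []
    for name, fitted in variants.items():
        row = {"configuration": name}
        for tag, cohort in (("internal", internal_test),
                            ("external", cohort_Q)):
            scores = fitted.risk_scores(cohort)
            reports = site_report({name: scores}, cohort, spec,
                                  horizon=horizon, seed=config.seed)
            o = reports[name].overall
            row[f"{tag}_cindex"] = o["cindex"]
            row[f"{tag}_ci_lower"] = o["lower"]
            row[f"{tag}_ci_upper"] = o["upper"]
        rows.append(row)
    table = pd.DataFrame(rows)
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "ablation_table.csv", index=False)
    return table
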