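"""Reference survival models: linear Cox PH and a DeepSurv-style MLP.

Both consume the 15 histopathology features only (no stage, site, or
latent class).  The linear model delegates to lifelines' CoxPHFitter; the
MLP shares the Cox partial-likelihood trainer of the hazard module but
has no latent input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .autoencoder import fit_scaler
from .io_tables import CohortTable, TrainingConfig
from .nn import MLP
from .riskmodel import _train_net

__all__ = ["BaselineModel", "fit_baseline", "baseline_predict"]


@dataclass
class BaselineModel:
    kind: str                         # "cox_linear" | "deepsurv_mlp"
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    coef: np.ndarray | None = None    # cox_linear
    kept_columns: np.ndarray | None = None
    net: MLP | None = None            # deepsurv_mlp


def fit_baseline(kind: str, cohort_P: CohortTable,
                 config: TrainingConfig | None = None,
                 val_cohort: CohortTable | None = None) -> BaselineModel:
    """Fit a baseline on the source cohort's features and outcomes."""
    config = config or TrainingConfig()
    if cohort_P.event.sum() == 0:
        raise ValueError("no events in the training cohort")
    x = cohort_P.features
    mean, sd = fit_scaler(x)
    x_std = (x - mean) / sd

    if kind == "cox_linear":
        keep = x.std(axis=0) > 1e-12
        if not keep.all():
            warnings.warn(
                f"dropping constant feature column(s) "
                f"{np.where(~keep)[0].tolist()} from the Cox model")
        cols = [f"x{i}" for i in np.where(keep)[0]]
        df = pd.DataFrame(x_std[:, keep], columns=cols)
        df["time"] = cohort_P.time
        df["event"] = cohort_P.event
        fitter = CoxPHFitter()
        fitter.fit(df, duration_col="time", event_col="event")
        coef = fitter.params_.to_numpy()
        return BaselineModel(kind=kind, scaler_mean=mean, scaler_sd=sd,
                             coef=coef, kept_columns=np.where(keep)[0])

    if kind == "deepsurv_mlp":
        rng = np.random.default_rng(config.seed + 4)
        net = MLP(x.shape[1], config.hazard_hidden, 1, rng)
        val = None
        if val_cohort is not None and len(val_cohort) > 0 \
                and val_cohort.event.sum() > 0:
            v_std = (val_cohort.features - mean) / sd
            val = (v_std, val_cohort.time, val_cohort.event)
        net, _ = _train_net(net, x_std, cohort_P.time, cohort_P.event,
                            config, rng, lr=config.learning_rate, val=val)
        return BaselineModel(kind=kind, scaler_mean=mean, scaler_sd=sd,
                             net=net)

    raise ValueError(f"unknown baseline kind {kind!r}")


def baseline_predict(model: BaselineModel, cohort: CohortTable) -> np.ndarray:
    """Deterministic per-patient log hazard-ratio risk scores."""
    x = cohort.features
    if x.shape[1] != len(model.scaler_mean):
        raise ValueError(
            f"expected {len(model.scaler_mean)} features, got {x.shape[1]}")
    x_std = (x - model.scaler_mean) / model.scaler_sd
    if model.kind == "cox_linear":
        return x_std[:, model.kept_columns] @ model.coef
    return model.net(x_std)[:, 0]
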