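"""Latent-estimation branch (Module B) and latent-shift ratio.

A small MLP predicts the frozen autoencoder's discrete latent label from
the features alone, trained with per-dimension sigmoid binary
cross-entropy against the one-hot labels.  Its renormalized outputs give
P(U=i | X); averaging posteriors over the source cohort gives the source
prevalence P(U), over a target cohort the target prevalence Q(U), and
their element-wise ratio is the latent-shift correction used to rescale
hazard predictions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autoencoder import EncoderState, assign_latents
from .io_tables import CohortTable, TrainingConfig
from .nn import MLP, Adam, sigmoid, softmax

__all__ = [
    "EstimatorState",
    "ShiftEstimate",
    "train_estimator",
    "posterior",
    "estimate_shift",
    "save_estimator",
    "load_estimator",
]


@dataclass
class ShiftEstimate:
    """Source/target latent prevalences and their ratio Q(U)/P(U)."""

    p_u: np.ndarray
    q_u: np.ndarray
    ratio: np.ndarray

    def __post_init__(self):
        self.p_u = np.asarray(self.p_u, dtype=float)
        self.q_u = np.asarray(self.q_u, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if not np.all(np.isfinite(self.ratio)) or np.any(self.ratio < 0):
            raise ValueError("shift ratio must be finite and nonnegative")

    @classmethod
    def identity(cls, k: int) -> "ShiftEstimate":
        u = np.full(k, 1.0 / k)
        return cls(u, u, np.ones(k))

    def to_dict(self) -> dict:
        return {"p_u": self.p_u.tolist(), "q_u": self.q_u.tolist(),
                "ratio": self.ratio.tolist()}


@dataclass
class EstimatorState:
    network: MLP
    k_u: int
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    source_prevalence: np.ndarray
    posterior_mode: str = "sigmoid"
    epsilon_prevalence: float = 1e-6
    trained: bool = False


def _raw_outputs(state: EstimatorState, x_std: np.ndarray) -> np.ndarray:
    z = state.network(x_std)
    if state.posterior_mode == "softmax":
        return softmax(z, axis=1)
    return sigmoid(z)


def posterior(state: EstimatorState, x: np.ndarray) -> np.ndarray:
    """P(U | X): estimator outputs renormalized onto the simplex."""
    if not state.trained:
        raise RuntimeError("estimator has not been trained")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(state.scaler_mean):
        raise ValueError(
            f"expected {len(state.scaler_mean)} features, got {x.shape[1]}")
    x_std = (x - state.scaler_mean) / state.scaler_sd
    raw = _raw_outputs(state, x_std)
    total = raw.sum(axis=1, keepdims=True)
    total[total <= 0] = 1.0
    return raw / total


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def train_estimator(cohort_P: CohortTable, ae_state: EncoderState,
                    config: TrainingConfig,
                    val_cohort: CohortTable | None = None) -> EstimatorState:
    """Fit Module B against the frozen autoencoder's hard labels.

    Trained with per-dimension sigmoid BCE (or softmax cross-entropy in
    the alternative posterior mode); if a validation cohort is given,
    early stopping monitors the validation loss like the other model
    components.
    """
    if len(cohort_P) == 0:
        raise ValueError("cohort is empty")
    if not ae_state.trained:
        raise RuntimeError("autoencoder must be trained first")
    rng = np.random.default_rng(config.seed + 1)
    labels = assign_latents(ae_state, cohort_P).hard
    k = ae_state.k_u
    y = np.eye(k)[labels]

    x = ae_state.standardize(cohort_P.features)
    n, d = x.shape
    net = MLP(d, config.estimator_hidden, k, rng)
    opt = Adam(net.params(), lr=config.learning_rate)

    val = None
    if val_cohort is not None and len(val_cohort) > 0:
        val = (ae_state.standardize(val_cohort.features),
               np.eye(k)[assign_latents(ae_state, val_cohort).hard])
    best_val, best_state = np.inf, None
    patience_left = config.early_stopping_patience

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            z = net.forward(x[idx])
            if config.posterior_mode == "softmax":
                p = softmax(z, axis=1)
                dz = (p - y[idx]) / len(idx)
            else:
                p = sigmoid(z)
                dz = (p - y[idx]) / (len(idx) * k)
            net.backward(dz)
            opt.step(net.grads())
        if val is not None:
            xv, yv = val
            zv = net(xv)
            pv = (softmax(zv, axis=1) if config.posterior_mode == "softmax"
                  else sigmoid(zv))
            vloss = _bce(pv, yv)
            if vloss < best_val - 1e-9:
                best_val, best_state = vloss, net.state()
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_state is not None:
        net = MLP.from_state(best_state)

    state = EstimatorState(
        network=net, k_u=k,
        scaler_mean=ae_state.scaler_mean, scaler_sd=ae_state.scaler_sd,
        source_prevalence=np.full(k, 1.0 / k),
        posterior_mode=config.posterior_mode,
        epsilon_prevalence=config.epsilon_prevalence,
        trained=True)
    state.source_prevalence = _prevalence(
        state, cohort_P.features, config.prevalence_mode)
    present = np.unique(labels)
    if len(present) < k:
        missing = sorted(set(range(k)) - set(present.tolist()))
        warnings.warn(
            f"latent class(es) {missing} absent from the training cohort; "
            "their prevalence will rely on the epsilon floor")
    return state


def _prevalence(state: EstimatorState, features: np.ndarray,
                mode: str = "soft") -> np.ndarray:
    post = posterior(state, features)
    if mode == "hard":
        counts = np.bincount(np.argmax(post, axis=1), minlength=state.k_u)
        return counts / counts.sum()
    return post.mean(axis=0)


def estimate_shift(state: EstimatorState, target_features: np.ndarray,
                   prevalence_mode: str = "soft") -> ShiftEstimate:
    """Estimate Q(U), and the ratio Q(U)/P(U) with a floored denominator."""
    target_features = np.atleast_2d(np.asarray(target_features, dtype=float))
    if target_features.shape[0] == 0:
        raise ValueError("target cohort is empty")
    q_u = _prevalence(state, target_features, prevalence_mode)
    p_u = state.source_prevalence
    ratio = q_u / np.maximum(p_u, state.epsilon_prevalence)
    return ShiftEstimate(p_u=p_u, q_u=q_u, ratio=ratio)


def save_estimator(state: EstimatorState, path: str | Path) -> None:
    payload = {
        "format": "causalsurv-est-v1",
        "k_u": state.k_u,
        "scaler_mean": state.scaler_mean.tolist(),
        "scaler_sd": state.scaler_sd.tolist(),
        "source_prevalence": state.source_prevalence.tolist(),
        "posterior_mode": state.posterior_mode,
        "epsilon_prevalence": state.epsilon_prevalence,
        "network": state.network.state(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_estimator(path: str | Path) -> EstimatorState:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format") != "causalsurv-est-v1":
        raise ValueError("not a causalsurv estimator checkpoint")
    return EstimatorState(
        network=MLP.from_state(d["network"]),
        k_u=d["k_u"],
        scaler_mean=np.asarray(d["scaler_mean"]),
        scaler_sd=np.asarray(d["scaler_sd"]),
        source_prevalence=np.asarray(d["source_prevalence"]),
        posterior_mode=d["posterior_mode"],
        epsilon_prevalence=d["epsilon_prevalence"],
        trained=True)
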