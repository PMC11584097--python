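"""Discrete-latent autoencoder guided by concept and proxy heads (Module A).

A single affine encoder maps the 15 standardized histopathology features
to ``k_u`` logits; Gumbel-softmax sampling with an annealed temperature
relaxes the categorical latent into a simplex vector that a single affine
decoder reconstructs the features from.  Two auxiliary affine classifiers
on the latent predict tumor stage (the concept C) and site of origin (the
proxy W), and a KL penalty toward the uniform prior discourages prior
collapse.  The training objective is

    L = beta_x * MSE(X, X_hat) + beta_c * CE(C, C_hat)
        + beta_w * CE(W, W_hat) + beta_kl * KL(U_hat || Uniform(k_u))
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import xlogy

from .io_tables import CohortTable, TrainingConfig
from .nn import Adam, Dense, log_softmax, softmax

__all__ = [
    "EncoderState",
    "LatentAssignment",
    "sample_gumbel",
    "gumbel_softmax",
    "autoencoder_loss",
    "train_autoencoder",
    "assign_latents",
    "save_encoder",
    "load_encoder",
]


def sample_gumbel(shape, rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(low=np.finfo(float).tiny, high=1.0, size=shape)
    return -np.log(-np.log(u))


def gumbel_softmax(logits: np.ndarray, temperature: float,
                   noise: np.ndarray | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Relaxed categorical sample: softmax((logits + g) / temperature).

    ``noise`` may be supplied explicitly (e.g. zeros for a deterministic
    check); otherwise standard Gumbel noise is drawn from ``rng``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    logits = np.asarray(logits, dtype=float)
    if noise is None:
        if rng is None:
            raise ValueError("provide either noise or rng")
        noise = sample_gumbel(logits.shape, rng)
    return softmax((logits + noise) / temperature, axis=-1)


def _cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    lsm = log_softmax(logits, axis=1)
    return float(-lsm[np.arange(len(labels)), labels].mean())


def _kl_to_uniform(p: np.ndarray, k: int) -> float:
    # sum p log(p k); xlogy handles p == 0
    return float(np.sum(xlogy(p, p * k)))


def autoencoder_loss(x, x_hat, c, c_logits, w, w_logits, u_soft,
                     config: TrainingConfig) -> tuple[float, dict]:
    """Composite autoencoder objective and its four parts.

    ``c`` and ``w`` are integer class indices; MSE averages over batch and
    feature dimensions, CE over the batch.  The KL term compares either
    the batch-mean latent distribution (default) or the per-sample mean KL
    against the uniform prior.
    """
    for name in ("beta_x", "beta_c", "beta_w", "beta_kl"):
        if getattr(config, name) < 0:
            raise ValueError(f"{name} must be nonnegative")
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    u_soft = np.asarray(u_soft, dtype=float)
    k = u_soft.shape[1]
    mse = float(np.mean((x - x_hat) ** 2))
    ce_c = _cross_entropy(np.asarray(c_logits), np.asarray(c))
    ce_w = _cross_entropy(np.asarray(w_logits), np.asarray(w))
    if config.kld_mode == "batch_mean":
        kld = _kl_to_uniform(u_soft.mean(axis=0), k)
    else:
        kld = float(np.mean(
            [_kl_to_uniform(row, k) for row in u_soft]))
    parts = {"mse": mse, "ce_c": ce_c, "ce_w": ce_w, "kld": kld}
    total = (config.beta_x * mse + config.beta_c * ce_c
             + config.beta_w * ce_w + config.beta_kl * kld)
    return total, parts


@dataclass
class LatentAssignment:
    """Soft posterior and hardened one-hot latent labels, row-aligned."""

    soft: np.ndarray     # (n, k_u)
    hard: np.ndarray     # (n,) int labels

    @property
    def onehot(self) -> np.ndarray:
        eye = np.eye(self.soft.shape[1])
        return eye[self.hard]


@dataclass
class EncoderState:
    """Frozen autoencoder: encoder/decoder plus the two auxiliary heads."""

    encoder: Dense
    decoder: Dense
    head_c: Dense
    head_w: Dense
    k_u: int
    temperature: float           # final (inference) temperature
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    stage_classes: list
    center_classes: list
    trained: bool = False
    history: list | None = None

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.scaler_mean) / self.scaler_sd


def _encode_labels(values: np.ndarray, classes: list) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(classes)}
    return np.array([lookup[v] for v in values], dtype=int)


def fit_scaler(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return mean, sd


def train_autoencoder(cohort: CohortTable, config: TrainingConfig,
                      val_cohort: CohortTable | None = None) -> EncoderState:
    """Fit Module A on a (training) cohort; deterministic given the seed.

    The Gumbel-softmax temperature decays exponentially from
    ``temperature_start`` to ``temperature_end`` over ``anneal_steps``
    gradient steps and is held there afterwards.  If a validation cohort
    is supplied, early stopping monitors the noise-free validation loss.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(config.seed)
    x_raw = cohort.features
    mean, sd = fit_scaler(x_raw)
    x = (x_raw - mean) / sd

    stage_classes = sorted(set(cohort.stage.tolist()))
    center_classes = sorted({str(c) for c in cohort.center})
    c_idx = _encode_labels(cohort.stage, stage_classes)
    w_idx = _encode_labels(np.array([str(c) for c in cohort.center]),
                           center_classes)

    beta_w = config.beta_w
    if len(center_classes) < 2 and beta_w > 0:
        warnings.warn("single center label: proxy head disabled")
        beta_w = 0.0
    beta_c = config.beta_c
    if len(stage_classes) < 2 and beta_c > 0:
        warnings.warn("single stage label: concept head disabled")
        beta_c = 0.0

    n, d = x.shape
    k = config.k_u
    enc = Dense(d, k, rng)
    dec = Dense(k, d, rng)
    head_c = Dense(k, max(len(stage_classes), 1), rng)
    head_w = Dense(k, max(len(center_classes), 1), rng)
    nets = [enc, dec, head_c, head_w]
    params = [p for m in nets for p in m.params()]
    opt = Adam(params, lr=config.learning_rate)

    ts, te = config.temperature_start, config.temperature_end

    def temp_at(step: int) -> float:
        frac = min(step / max(config.anneal_steps, 1), 1.0)
        return float(ts * (te / ts) ** frac)

    val = None
    if val_cohort is not None and len(val_cohort) > 0:
        val = ((val_cohort.features - mean) / sd,
               _encode_labels(val_cohort.stage, stage_classes),
               _encode_labels(
                   np.array([str(c) for c in val_cohort.center]),
                   center_classes))

    eff = TrainingConfig(**{**config.to_dict(),
                            "beta_c": beta_c, "beta_w": beta_w})

    def eval_loss(xe, ce, we, temperature) -> float:
        logits = enc(xe)
        u = softmax(logits / temperature, axis=1)
        total, _ = autoencoder_loss(xe, dec(u), ce, head_c(u),
                                    we, head_w(u), u, eff)
        return total

    best_val = np.inf
    best_state = None
    patience_left = config.early_stopping_patience
    history = []
    step = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, cb, wb = x[idx], c_idx[idx], w_idx[idx]
            tau = temp_at(step)
            step += 1
            B = len(idx)

            logits = enc.forward(xb)
            g = sample_gumbel(logits.shape, rng)
            u = softmax((logits + g) / tau, axis=1)
            if config.straight_through:
                u_fwd = np.eye(k)[np.argmax(u, axis=1)]
            else:
                u_fwd = u
            x_hat = dec.forward(u_fwd)
            cl = head_c.forward(u_fwd)
            wl = head_w.forward(u_fwd)
            total, parts = autoencoder_loss(xb, x_hat, cb, cl, wb, wl,
                                            u, eff)
            ep_loss += total
            n_batches += 1

            # backward
            d_xhat = eff.beta_x * 2.0 * (x_hat - xb) / x_hat.size
            du = dec.backward(d_xhat)
            if eff.beta_c > 0:
                p_c = softmax(cl, axis=1)
                p_c[np.arange(B), cb] -= 1.0
                du += head_c.backward(eff.beta_c * p_c / B)
            if eff.beta_w > 0:
                p_w = softmax(wl, axis=1)
                p_w[np.arange(B), wb] -= 1.0
                du += head_w.backward(eff.beta_w * p_w / B)
            if eff.beta_kl > 0:
                if config.kld_mode == "batch_mean":
                    ubar = np.maximum(u.mean(axis=0), 1e-30)
                    du += eff.beta_kl * (np.log(ubar * k) + 1.0) / B
                else:
                    us = np.maximum(u, 1e-30)
                    du += eff.beta_kl * (np.log(us * k) + 1.0) / (B)
            # straight-through passes gradients to the soft sample
            dz = u * (du - np.sum(du * u, axis=1, keepdims=True))
            enc.backward(dz / tau)
            opt.step([g_ for m in nets for g_ in m.grads()])

        history.append({"epoch": epoch, "loss": ep_loss / max(n_batches, 1),
                        "temperature": temp_at(step)})
        if val is not None:
            vloss = eval_loss(*val, temperature=temp_at(step))
            history[-1]["val_loss"] = vloss
            if vloss < best_val - 1e-9:
                best_val = vloss
                best_state = [m.state() for m in nets]
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    if best_state is not None:
        enc, dec, head_c, head_w = [Dense.from_state(s) for s in best_state]

    return EncoderState(
        encoder=enc, decoder=dec, head_c=head_c, head_w=head_w,
        k_u=k, temperature=te, scaler_mean=mean, scaler_sd=sd,
        stage_classes=stage_classes, center_classes=center_classes,
        trained=True, history=history)


def assign_latents(state: EncoderState, cohort: CohortTable
                   ) -> LatentAssignment:
    """Deterministic latents from a frozen autoencoder.

    No Gumbel noise is injected at inference: the soft assignment is
    softmax(logits / final_temperature) and the hard label its argmax
    (lowest index wins ties).
    """
    if not state.trained:
        raise RuntimeError("autoencoder has not been trained")
    x = state.standardize(cohort.features)
    logits = state.encoder(x)
    soft = softmax(logits / state.temperature, axis=1)
    hard = np.argmax(soft, axis=1)
    return LatentAssignment(soft=soft, hard=hard)


def save_encoder(state: EncoderState, path: str | Path) -> None:
    payload = {
        "format": "causalsurv-ae-v1",
        "k_u": state.k_u,
        "temperature": state.temperature,
        "scaler_mean": state.scaler_mean.tolist(),
        "scaler_sd": state.scaler_sd.tolist(),
        "stage_classes": state.stage_classes,
        "center_classes": state.center_classes,
        "encoder": state.encoder.state(),
        "decoder": state.decoder.state(),
        "head_c": state.head_c.state(),
        "head_w": state.head_w.state(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_encoder(path: str | Path) -> EncoderState:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format") != "causalsurv-ae-v1":
        raise ValueError("not a causalsurv autoencoder checkpoint")
    return EncoderState(
        encoder=Dense.from_state(d["encoder"]),
        decoder=Dense.from_state(d["decoder"]),
        head_c=Dense.from_state(d["head_c"]),
        head_w=Dense.from_state(d["head_w"]),
        k_u=d["k_u"], temperature=d["temperature"],
        scaler_mean=np.asarray(d["scaler_mean"]),
        scaler_sd=np.asarray(d["scaler_sd"]),
        stage_classes=d["stage_classes"],
        center_classes=d["center_classes"],
        trained=True)
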