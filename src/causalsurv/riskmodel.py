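"""Shift-adjusted hazard model over features and latent class (Module C).

A small MLP maps (standardized features, one-hot latent class) to a log
hazard ratio and is trained by minimizing the Cox negative log partial
likelihood (Breslow handling of tied event times).  The baseline
cumulative hazard H0(t) is the Breslow estimator on the training risk
scores.  At inference the hazard ratio for a target-domain patient is the
posterior-weighted mixture over latent classes, rescaled by the estimated
latent-shift ratio:

    r_Q(x) = sum_i HR(x, U=i) * P(U=i | x) * Q(U=i) / P(U=i)

so the predicted survival curve is S(t | x) = exp(-H0(t) * r(x)).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from .autoencoder import fit_scaler
from .estimator import EstimatorState, ShiftEstimate, posterior
from .io_tables import CohortTable, TrainingConfig
from .nn import MLP, Adam

__all__ = [
    "RiskModelBundle",
    "cox_partial_nll",
    "breslow_baseline",
    "StepFunction",
    "train_risk_model",
    "shift_adjusted_risk",
    "finetune_on_estimated_latents",
    "predict",
    "save_risk_model",
    "load_risk_model",
]


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)
# ---------------------------------------------------------------------------

def cox_partial_nll(eta: np.ndarray, times: np.ndarray, events: np.ndarray,
                    return_grad: bool = False):
    """Negative log Cox partial likelihood (mean per event) and gradient.

    Breslow's treatment of ties: all events at a time share the risk set
    of subjects still under observation at that time.
    """
    eta = np.asarray(eta, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("no events in the data")

    order = np.argsort(-times, kind="stable")  # descending time
    t_s, e_s, eta_s = times[order], events[order], eta[order]
    # running log-sum-exp of eta over the risk set (times >= t)
    run_lse = np.logaddexp.accumulate(
        np.concatenate([[-np.inf], eta_s]))[1:]
    # subjects tied on time share the same risk set: take the value at the
    # last index of each tie group
    last_of_group = np.concatenate([t_s[1:] != t_s[:-1], [True]])
    group_lse = run_lse.copy()
    idx_last = np.where(last_of_group)[0]
    prev = 0
    for j in idx_last:
        group_lse[prev:j + 1] = run_lse[j]
        prev = j + 1

    ev = e_s == 1
    nll = float(-(eta_s[ev] - group_lse[ev]).sum() / n_events)
    if not return_grad:
        return nll
    # dNLL/deta_j = (-delta_j + exp(eta_j) * sum_{events i: t_i <= t_j} 1/D_i) / n_events
    inv_d = np.where(ev, np.exp(-group_lse), 0.0)
    # events appear in descending-time order; cumulative sum from the end
    # gives, at position j, the sum over events with t_i <= t_j
    cum_inv_d = np.cumsum(inv_d[::-1])[::-1]
    # correct within tie groups: every member of a tie group must include
    # all events at its own time
    start = 0
    for j in idx_last:
        cum_inv_d[start:j + 1] = cum_inv_d[start]
        start = j + 1
    grad_s = (-e_s + np.exp(eta_s) * cum_inv_d) / n_events
    grad = np.empty_like(grad_s)
    grad[order] = grad_s
    return nll, grad


class StepFunction:
    """Right-continuous nondecreasing step function, 0 before first knot."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float),
                              side="right")
        padded = np.concatenate([[0.0], self.y])
        return padded[idx]


def breslow_baseline(times: np.ndarray, events: np.ndarray,
                     eta: np.ndarray) -> StepFunction:
    """Breslow estimate of the baseline cumulative hazard H0(t)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    eta = np.asarray(eta, dtype=float)
    uniq = np.unique(times[events == 1])
    increments = np.empty(len(uniq))
    for i, t in enumerate(uniq):
        d = int(((times == t) & (events == 1)).sum())
        denom = np.exp(eta[times >= t]).sum()
        increments[i] = d / denom
    return StepFunction(uniq, np.cumsum(increments))


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class RiskModelBundle:
    hazard_net: MLP
    k_u: int
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    shift: ShiftEstimate | None = None
    latent_input: bool = True       # net consumes (x, onehot u)
    feature_input: bool = True      # net consumes x at all
    trained: bool = False
    history: list = field(default_factory=list)

    @property
    def baseline(self) -> StepFunction:
        return StepFunction(self.baseline_times, self.baseline_cumhaz)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.scaler_mean) / self.scaler_sd

    def _net_input(self, x_std: np.ndarray, u_onehot: np.ndarray | None
                   ) -> np.ndarray:
        parts = []
        if self.feature_input:
            parts.append(x_std)
        if self.latent_input:
            if u_onehot is None:
                raise ValueError("latent input required")
            parts.append(u_onehot)
        return np.concatenate(parts, axis=1)

    def log_hr(self, x: np.ndarray, u_onehot: np.ndarray | None = None
               ) -> np.ndarray:
        """Log hazard ratio eta(x, u)."""
        if not self.trained:
            raise RuntimeError("risk model has not been trained")
        x_std = self.standardize(np.atleast_2d(x))
        return self.hazard_net(self._net_input(x_std, u_onehot))[:, 0]


def _train_net(net: MLP, inputs: np.ndarray, times: np.ndarray,
               events: np.ndarray, config: TrainingConfig,
               rng: np.random.Generator, lr: float,
               val: tuple | None = None) -> tuple[MLP, list]:
    opt = Adam(net.params(), lr=lr, weight_decay=config.weight_decay)
    n = len(times)
    best_val, best_state = np.inf, None
    patience_left = config.early_stopping_patience
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if events[idx].sum() == 0:
                continue  # a batch with no events carries no likelihood
            eta = net.forward(inputs[idx], dropout=config.dropout,
                              rng=rng)[:, 0]
            nll, grad = cox_partial_nll(eta, times[idx], events[idx],
                                        return_grad=True)
            net.backward(grad[:, None])
            opt.step(net.grads())
            ep_loss += nll
            n_batches += 1
        rec = {"epoch": epoch, "loss": ep_loss / max(n_batches, 1)}
        if val is not None:
            v_inputs, v_times, v_events = val
            v_eta = net(v_inputs)[:, 0]
            vloss = cox_partial_nll(v_eta, v_times, v_events)
            rec["val_loss"] = vloss
            history.append(rec)
            if vloss < best_val - 1e-9:
                best_val, best_state = vloss, net.state()
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        else:
            history.append(rec)
    if best_state is not None:
        net = MLP.from_state(best_state)
    return net, history


def train_risk_model(cohort_P: CohortTable, latents_onehot: np.ndarray,
                     config: TrainingConfig,
                     val_cohort: CohortTable | None = None,
                     val_latents_onehot: np.ndarray | None = None,
                     feature_input: bool = True,
                     latent_input: bool = True) -> RiskModelBundle:
    """Fit the hazard net on the source cohort with its latent labels.

    ``latents_onehot`` must be row-aligned with ``cohort_P``.  Setting
    ``feature_input``/``latent_input`` restricts the net to one input
    block (used by the ablation configurations).
    """
    times, events = cohort_P.time, cohort_P.event
    if events.sum() == 0:
        raise ValueError("no events in the training cohort")
    if len(np.unique(times)) == 1:
        warnings.warn("all event times identical; Breslow ties apply")
    if latent_input and (latents_onehot is None
                         or len(latents_onehot) != len(cohort_P)):
        raise ValueError("latents must align with cohort rows")

    rng = np.random.default_rng(config.seed + 2)
    mean, sd = fit_scaler(cohort_P.features)
    x_std = (cohort_P.features - mean) / sd

    k = config.k_u if latent_input else 0
    if latent_input:
        k = latents_onehot.shape[1]
    n_in = (x_std.shape[1] if feature_input else 0) + k
    net = MLP(n_in, config.hazard_hidden, 1, rng)

    bundle = RiskModelBundle(
        hazard_net=net, k_u=max(k, 1), scaler_mean=mean, scaler_sd=sd,
        baseline_times=np.empty(0), baseline_cumhaz=np.empty(0),
        latent_input=latent_input, feature_input=feature_input,
        trained=False)
    inputs = bundle._net_input(x_std, latents_onehot if latent_input else None)

    val = None
    if val_cohort is not None and len(val_cohort) > 0 \
            and val_cohort.event.sum() > 0:
        v_std = (val_cohort.features - mean) / sd
        v_in = bundle._net_input(
            v_std, val_latents_onehot if latent_input else None)
        val = (v_in, val_cohort.time, val_cohort.event)

    net, history = _train_net(net, inputs, times, events, config, rng,
                              lr=config.learning_rate, val=val)
    bundle.hazard_net = net
    bundle.trained = True
    bundle.history = history

    eta = net(inputs)[:, 0]
    h0 = breslow_baseline(times, events, eta)
    bundle.baseline_times, bundle.baseline_cumhaz = h0.x, h0.y
    return bundle


# ---------------------------------------------------------------------------
# Shift adjustment
# ---------------------------------------------------------------------------

def shift_adjusted_risk(bundle: RiskModelBundle, x: np.ndarray,
                        post: np.ndarray, shift: ShiftEstimate,
                        normalize: bool = False) -> np.ndarray:
    """Posterior- and shift-weighted mixture hazard ratio r_Q(x).

    With ``normalize`` the weights posterior * ratio are renormalized to
    sum to one per patient (a statistically coherent variant); the default
    applies the ratio as printed, without renormalization.
    """
    if not bundle.trained:
        raise RuntimeError("risk model has not been trained")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    post = np.atleast_2d(np.asarray(post, dtype=float))
    k = post.shape[1]
    if len(shift.ratio) != k:
        raise ValueError("posterior and shift ratio disagree on k_u")
    if bundle.latent_input and k != bundle.k_u:
        raise ValueError("posterior k_u does not match the model")

    weights = post * shift.ratio[None, :]
    if normalize:
        tot = weights.sum(axis=1, keepdims=True)
        tot[tot <= 0] = 1.0
        weights = weights / tot

    if not bundle.latent_input:
        # no latent input: the mixture collapses to a single evaluation
        return np.exp(bundle.log_hr(x)) * weights.sum(axis=1)

    eye = np.eye(k)
    hr = np.empty((x.shape[0], k))
    for i in range(k):
        onehot = np.tile(eye[i], (x.shape[0], 1))
        hr[:, i] = np.exp(bundle.log_hr(x, onehot))
    return (hr * weights).sum(axis=1)


def finetune_on_estimated_latents(bundle: RiskModelBundle,
                                  cohort_P: CohortTable,
                                  estimator: EstimatorState,
                                  config: TrainingConfig,
                                  val_cohort: CohortTable | None = None
                                  ) -> RiskModelBundle:
    """Continue training on source data with estimator-derived latents.

    The autoencoder latents are replaced by the hard argmax of the
    estimator posterior (what will be available in the target domain),
    at a reduced learning rate with early stopping on the validation
    partial likelihood.
    """
    if not bundle.trained or not estimator.trained:
        raise RuntimeError("bundle and estimator must be trained")
    rng = np.random.default_rng(config.seed + 3)
    x_std = bundle.standardize(cohort_P.features)
    post = posterior(estimator, cohort_P.features)
    onehot = np.eye(post.shape[1])[np.argmax(post, axis=1)]
    inputs = bundle._net_input(x_std, onehot if bundle.latent_input else None)

    val = None
    if val_cohort is not None and len(val_cohort) > 0 \
            and val_cohort.event.sum() > 0:
        v_post = posterior(estimator, val_cohort.features)
        v_onehot = np.eye(v_post.shape[1])[np.argmax(v_post, axis=1)]
        v_in = bundle._net_input(
            bundle.standardize(val_cohort.features),
            v_onehot if bundle.latent_input else None)
        val = (v_in, val_cohort.time, val_cohort.event)

    net = bundle.hazard_net.copy()
    net, history = _train_net(
        net, inputs, cohort_P.time, cohort_P.event, config, rng,
        lr=config.learning_rate * config.finetune_lr_factor, val=val)
    bundle.hazard_net = net
    bundle.history = bundle.history + history

    eta = net(inputs)[:, 0]
    h0 = breslow_baseline(cohort_P.time, cohort_P.event, eta)
    bundle.baseline_times, bundle.baseline_cumhaz = h0.x, h0.y
    return bundle


def predict(bundle: RiskModelBundle, cohort: CohortTable, mode: str,
            estimator: EstimatorState | None = None,
            shift: ShiftEstimate | None = None,
            latents_onehot: np.ndarray | None = None,
            month_grid: np.ndarray | None = None,
            normalize: bool | None = None) -> dict:
    """Per-patient risk scores and survival curves.

    ``mode='unadjusted'`` returns the posterior-weighted mixture hazard
    ratio (ratio identically one); ``mode='adjusted'`` applies the
    latent-shift ratio.  When the model has a latent input and no
    estimator is given, ``latents_onehot`` (e.g. autoencoder assignments)
    must be provided and the mixture reduces to those labels.
    """
    if mode not in ("unadjusted", "adjusted"):
        raise ValueError("mode must be 'unadjusted' or 'adjusted'")
    if mode == "adjusted" and shift is None:
        raise ValueError("adjusted mode requires a ShiftEstimate")
    x = cohort.features
    n = len(cohort)

    if bundle.latent_input:
        if estimator is not None:
            post = posterior(estimator, x)
        elif latents_onehot is not None:
            post = latents_onehot
        else:
            raise ValueError("latent input requires estimator or latents")
    else:
        post = np.ones((n, 1))

    if mode == "adjusted":
        eff_shift = shift
    else:
        eff_shift = ShiftEstimate.identity(post.shape[1])
    if normalize is None:
        normalize = False
    risk = shift_adjusted_risk(bundle, x, post, eff_shift,
                               normalize=normalize)

    if month_grid is None:
        month_grid = np.arange(0.0, 61.0)
    h0 = bundle.baseline(month_grid)
    survival = np.exp(-np.outer(risk, h0))
    return {"risk": risk, "month_grid": np.asarray(month_grid, dtype=float),
            "survival": survival}


def save_risk_model(bundle: RiskModelBundle, path: str | Path) -> None:
    payload = {
        "format": "causalsurv-risk-v1",
        "k_u": bundle.k_u,
        "scaler_mean": bundle.scaler_mean.tolist(),
        "scaler_sd": bundle.scaler_sd.tolist(),
        "baseline_times": bundle.baseline_times.tolist(),
        "baseline_cumhaz": bundle.baseline_cumhaz.tolist(),
        "latent_input": bundle.latent_input,
        "feature_input": bundle.feature_input,
        "network": bundle.hazard_net.state(),
        "shift": bundle.shift.to_dict() if bundle.shift else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_risk_model(path: str | Path) -> RiskModelBundle:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format") != "causalsurv-risk-v1":
        raise ValueError("not a causalsurv risk-model checkpoint")
    shift = None
    if d.get("shift"):
        s = d["shift"]
        shift = ShiftEstimate(np.asarray(s["p_u"]), np.asarray(s["q_u"]),
                              np.asarray(s["ratio"]))
    return RiskModelBundle(
        hazard_net=MLP.from_state(d["network"]),
        k_u=d["k_u"],
        scaler_mean=np.asarray(d["scaler_mean"]),
        scaler_sd=np.asarray(d["scaler_sd"]),
        baseline_times=np.asarray(d["baseline_times"]),
        baseline_cumhaz=np.asarray(d["baseline_cumhaz"]),
        shift=shift,
        latent_input=d["latent_input"],
        feature_input=d["feature_input"],
        trained=True)
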