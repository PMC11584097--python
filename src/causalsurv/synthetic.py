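"""Synthetic multi-site survival cohorts with a hidden subgroup.

The generator realizes the latent-shift causal graph: a discrete subgroup
U drives the histopathology feature vector X, the tumor stage C, the site
of origin W, and the recurrence hazard.  Source (P) and target (Q) domains
share every structural distribution except the marginal of U, so the only
difference between domains is the subgroup mix.  Hidden columns (the true
subgroup, linear predictor, and uncensored event time) are emitted for
testing and are never consumed by the models.

Event times follow a Weibull proportional-hazards model
``h(t | x, u) = h0(t) * exp(b_x . x_std + b_u[u] + b_stage[c])`` with
administrative uniform censoring on ``[0, censor_max]``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import CohortSchema, CohortTable

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_domain",
    "default_multisite_config",
    "two_class_shift_config",
]

N_FEATURES = 15
TIL_INDEX = 8  # TILs per mm^2: nonnegative, not a percentage


@dataclass
class SimulationConfig:
    k_true: int
    pi_P: np.ndarray
    pi_Q: np.ndarray
    class_feature_means: np.ndarray      # (k_true, 15)
    class_feature_sds: np.ndarray        # (k_true, 15)
    stage_probs: np.ndarray              # (k_true, 3), P(C | U)
    center_probs_P: np.ndarray           # (k_true, n_centers_P)
    center_probs_Q: np.ndarray           # (k_true, n_centers_Q)
    feature_loghr: np.ndarray            # (15,), effect of standardized X
    class_loghr: np.ndarray              # (k_true,), direct effect of U
    baseline_scale: float = 100.0        # Weibull scale (months)
    baseline_shape: float = 1.2
    censor_max: float = 60.0
    n_P: int = 2411
    n_Q: int = 938
    seed: int = 0
    stage_effect: bool = True
    stage_loghr: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.2, 0.4]))
    centers_P: tuple[str, ...] | None = None
    centers_Q: tuple[str, ...] | None = None
    split_fractions: tuple[float, float, float] = (0.60, 0.10, 0.30)

    def __post_init__(self):
        for name in ("pi_P", "pi_Q", "class_feature_means",
                     "class_feature_sds", "stage_probs", "center_probs_P",
                     "center_probs_Q", "feature_loghr", "class_loghr",
                     "stage_loghr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.pi_P) != self.k_true or len(self.pi_Q) != self.k_true:
            raise ValueError("pi_P/pi_Q length must equal k_true")
        for name in ("pi_P", "pi_Q"):
            v = getattr(self, name)
            if abs(v.sum() - 1.0) > 1e-12 or (v < 0).any():
                raise ValueError(f"{name} must be a probability vector")
        for name in ("stage_probs", "center_probs_P", "center_probs_Q"):
            m = getattr(self, name)
            if m.shape[0] != self.k_true:
                raise ValueError(f"{name} must have k_true rows")
            if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-12 or (m < 0).any():
                raise ValueError(f"rows of {name} must sum to 1")
        if self.class_feature_means.shape != (self.k_true, N_FEATURES):
            raise ValueError("class_feature_means must be (k_true, 15)")
        if self.class_feature_sds.shape != (self.k_true, N_FEATURES):
            raise ValueError("class_feature_sds must be (k_true, 15)")
        if (self.class_feature_sds <= 0).any():
            raise ValueError("class_feature_sds must be positive")
        if self.n_P < 1 or self.n_Q < 1:
            raise ValueError("n_P and n_Q must be >= 1")
        if self.centers_P is None:
            self.centers_P = tuple(
                f"siteP{i + 1}" for i in range(self.center_probs_P.shape[1]))
        if self.centers_Q is None:
            self.centers_Q = tuple(
                f"siteQ{i + 1}" for i in range(self.center_probs_Q.shape[1]))

    def mixture_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Population mean/sd of X under the SOURCE mix (used to
        standardize features inside the hazard, identically in both
        domains so the structural model is domain-invariant)."""
        mu = self.pi_P @ self.class_feature_means
        second = self.pi_P @ (self.class_feature_sds ** 2
                              + self.class_feature_means ** 2)
        sd = np.sqrt(np.maximum(second - mu ** 2, 1e-12))
        return mu, sd

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("centers_P", "centers_Q"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(**d)


@dataclass
class SimulatedCohort:
    """A generated cohort plus its hidden ground truth."""

    table: CohortTable
    u_true: np.ndarray
    true_risk: np.ndarray        # linear predictor (log hazard ratio)
    t_uncensored: np.ndarray

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.table.df[self.table.schema.id_col],
            "u_true": self.u_true,
            "true_risk": self.true_risk,
            "t_uncensored": self.t_uncensored,
        })


def _assign_splits(n: int, fractions: tuple[float, float, float],
                   rng: np.random.Generator) -> np.ndarray:
    labels = np.empty(n, dtype=object)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    labels[perm[:n_train]] = "internal-train"
    labels[perm[n_train:n_train + n_val]] = "internal-val"
    labels[perm[n_train + n_val:]] = "internal-test"
    return labels


def _categorical_rows(prob_rows: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a (n, k) probability matrix."""
    cum = np.cumsum(prob_rows, axis=1)
    r = rng.uniform(size=(prob_rows.shape[0], 1))
    return np.minimum((r >= cum[:, :-1]).sum(axis=1),
                      prob_rows.shape[1] - 1).astype(int)


def simulate_domain(config: SimulationConfig, domain: str) -> SimulatedCohort:
    """Draw one cohort from the configured graph for domain ``P`` or ``Q``."""
    if domain not in ("P", "Q"):
        raise ValueError("domain must be 'P' or 'Q'")
    is_p = domain == "P"
    n = config.n_P if is_p else config.n_Q
    pi = config.pi_P if is_p else config.pi_Q
    center_probs = config.center_probs_P if is_p else config.center_probs_Q
    centers = config.centers_P if is_p else config.centers_Q
    rng = np.random.default_rng([config.seed, 0 if is_p else 1])

    u = rng.choice(config.k_true, size=n, p=pi)
    x = rng.normal(config.class_feature_means[u],
                   config.class_feature_sds[u])
    # truncate to valid feature ranges: percentages in [0, 100],
    # TIL density only floored at 0
    lo = np.zeros(N_FEATURES)
    hi = np.full(N_FEATURES, 100.0)
    hi[TIL_INDEX] = np.inf
    x = np.clip(x, lo, hi)

    stage = _categorical_rows(config.stage_probs[u], rng) + 1
    center_idx = _categorical_rows(center_probs[u], rng)
    center = np.asarray(centers, dtype=object)[center_idx]

    mu, sd = config.mixture_moments()
    x_std = (x - mu) / sd
    lin = x_std @ config.feature_loghr + config.class_loghr[u]
    if config.stage_effect:
        lin = lin + config.stage_loghr[stage - 1]
    hr = np.exp(lin)

    # inverse-CDF Weibull PH sampling: S(t) = exp(-(t/b)^a * hr)
    v = rng.uniform(size=n)
    t_event = config.baseline_scale * (-np.log(v) / hr) ** (
        1.0 / config.baseline_shape)
    censor = rng.uniform(0.0, config.censor_max, size=n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    time = np.maximum(time, 1e-3)  # strictly positive follow-up

    split = (_assign_splits(n, config.split_fractions, rng) if is_p
             else np.full(n, "external-test", dtype=object))
    prefix = "P" if is_p else "Q"
    df = pd.DataFrame({"patient_id": [f"{prefix}{i:06d}" for i in range(n)]})
    schema = CohortSchema()
    for j, col in enumerate(schema.feature_cols):
        df[col] = x[:, j]
    df["stage"] = stage
    df["center"] = center
    df["time"] = time
    df["event"] = event
    df["split"] = split
    table = CohortTable(df, schema)
    return SimulatedCohort(table, u, lin, t_event)


def default_multisite_config(seed: int = 0) -> SimulationConfig:
    """Preset mirroring the study's cohort shape.

    ~2,400 internal patients across five sites, ~950 external across
    three, three latent subgroups, and an overall stage mix of roughly
    20% / 40% / 40%.
    """
    k = 3
    pi_P = np.array([0.5, 0.3, 0.2])
    pi_Q = np.array([0.2, 0.3, 0.5])
    rng = np.random.default_rng(20240303)
    base = np.array([35.0, 30.0, 30.0, 8.0, 5.0, 6.0, 12.0, 1.0,
                     250.0, 15.0, 10.0, 20.0, 30.0, 20.0, 45.0])
    offsets = rng.normal(0.0, 1.0, size=(k, N_FEATURES))
    spread = np.array([8.0, 7.0, 6.0, 4.0, 3.0, 3.5, 5.0, 0.8,
                       120.0, 6.0, 4.0, 7.0, 9.0, 7.0, 10.0])
    # subgroup centroids one within-class sd apart on average: the
    # subgroup is informative about risk but not identifiable from the
    # features with certainty (the regime latent-shift adjustment targets)
    means = base + offsets * spread
    means[:, TIL_INDEX] = np.abs(means[:, TIL_INDEX])
    sds = np.tile(spread, (k, 1))
    stage_probs = np.array([
        [0.32, 0.45, 0.23],
        [0.10, 0.40, 0.50],
        [0.05, 0.28, 0.67],
    ])
    centers_P = ("Ontario", "Mayo", "Seattle", "Australia", "Hawaii")
    centers_Q = ("UPMC", "MtSinai", "ACCESS")
    center_probs_P = np.array([
        [0.55, 0.15, 0.15, 0.12, 0.03],
        [0.30, 0.30, 0.25, 0.10, 0.05],
        [0.20, 0.25, 0.25, 0.25, 0.05],
    ])
    center_probs_Q = np.array([
        [0.65, 0.25, 0.10],
        [0.40, 0.45, 0.15],
        [0.25, 0.50, 0.25],
    ])
    feature_loghr = np.zeros(N_FEATURES)
    feature_loghr[[0, 3, 8, 10]] = [0.15, 0.25, -0.20, 0.15]
    class_loghr = np.array([-0.8, 0.1, 0.9])
    return SimulationConfig(
        k_true=k, pi_P=pi_P, pi_Q=pi_Q,
        class_feature_means=means, class_feature_sds=sds,
        stage_probs=stage_probs,
        center_probs_P=center_probs_P, center_probs_Q=center_probs_Q,
        feature_loghr=feature_loghr, class_loghr=class_loghr,
        baseline_scale=100.0, baseline_shape=1.2, censor_max=60.0,
        n_P=2411, n_Q=938, seed=seed,
        centers_P=centers_P, centers_Q=centers_Q,
    )


def two_class_shift_config(seed: int = 0, n_P: int = 5000, n_Q: int = 5000,
                           shift: bool = True,
                           separation: float = 2.0) -> SimulationConfig:
    """Two-subgroup scenario with a strong prevalence flip.

    The source mixes the subgroups 80/20 and the target 20/80; five of the
    fifteen features separate the subgroups by ``separation`` standard
    deviations, and the recurrence hazard is carried by the subgroup alone
    (class log-HR -0.8 / +0.8, zero within-class feature effect).  With
    ``shift=False`` the target keeps the source mix (a no-shift control).
    """
    k = 2
    pi_P = np.array([0.8, 0.2])
    pi_Q = np.array([0.2, 0.8]) if shift else pi_P.copy()
    sds = np.full((k, N_FEATURES), 8.0)
    sds[:, TIL_INDEX] = 120.0
    means = np.tile(
        np.array([35.0, 30.0, 25.0, 10.0, 8.0, 8.0, 12.0, 4.0,
                  300.0, 15.0, 10.0, 20.0, 30.0, 20.0, 45.0]), (k, 1))
    informative = [0, 2, 5, 9, 12]
    means[1, informative] += separation * sds[0, informative]
    stage_probs = np.array([
        [0.30, 0.45, 0.25],
        [0.10, 0.35, 0.55],
    ])
    center_probs_P = np.array([
        [0.50, 0.30, 0.20],
        [0.15, 0.25, 0.60],
    ])
    center_probs_Q = np.array([
        [0.70, 0.30],
        [0.35, 0.65],
    ])
    return SimulationConfig(
        k_true=k, pi_P=pi_P, pi_Q=pi_Q,
        class_feature_means=means, class_feature_sds=sds,
        stage_probs=stage_probs,
        center_probs_P=center_probs_P, center_probs_Q=center_probs_Q,
        feature_loghr=np.zeros(N_FEATURES),
        class_loghr=np.array([-0.8, 0.8]),
        baseline_scale=100.0, baseline_shape=1.2, censor_max=60.0,
        n_P=n_P, n_Q=n_Q, seed=seed,
    )


def write_simulation(config: SimulationConfig, out_prefix: str | Path
                     ) -> dict[str, Path]:
    """Emit P.csv, Q.csv, truth.csv, and the resolved config."""
    import json

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    sim_p = simulate_domain(config, "P")
    sim_q = simulate_domain(config, "Q")
    paths = {
        "P": out_prefix.with_name(out_prefix.name + "_P.csv"),
        "Q": out_prefix.with_name(out_prefix.name + "_Q.csv"),
        "truth": out_prefix.with_name(out_prefix.name + "_truth.csv"),
        "config": out_prefix.with_name(out_prefix.name + "_simconfig.json"),
    }
    sim_p.table.df.to_csv(paths["P"], index=False)
    sim_q.table.df.to_csv(paths["Q"], index=False)
    truth = pd.concat([sim_p.truth_frame(), sim_q.truth_frame()],
                      ignore_index=True)
    truth.to_csv(paths["truth"], index=False)
    with open(paths["config"], "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    return paths
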