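"""Cohort tables, configuration objects, and result reports.

The shared data model: one row per patient with 15 quantitative
histopathology features (QuantCRC-style), an ordinal tumor stage (the
concept variable C), a categorical treatment site (the proxy variable W),
follow-up time in months, and a binary recurrence indicator.  Reading is
strict: malformed rows are rejected with their indices, never silently
dropped or imputed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SPLITS = ("internal-train", "internal-val", "internal-test", "external-test")

__all__ = [
    "SPLITS",
    "CohortSchema",
    "CohortTable",
    "CohortValidationError",
    "TrainingConfig",
    "EvalReport",
    "read_cohort",
    "write_cohort",
    "write_report",
    "read_report",
    "load_config_file",
]


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the schema; carries row indices."""

    def __init__(self, messages: list[str]):
        self.messages = messages
        super().__init__("; ".join(messages))


@dataclass(frozen=True)
class CohortSchema:
    """Column naming and label sets for a cohort table."""

    id_col: str = "patient_id"
    time_col: str = "time"
    event_col: str = "event"
    stage_col: str = "stage"
    center_col: str = "center"
    split_col: str = "split"
    n_features: int = 15
    feature_cols: tuple[str, ...] = ()
    stages: tuple[int, ...] = (1, 2, 3)
    centers: tuple[str, ...] | None = None  # None -> any label accepted

    def __post_init__(self):
        if not self.feature_cols:
            object.__setattr__(
                self, "feature_cols",
                tuple(f"feat_{i + 1}" for i in range(self.n_features)))
        if len(self.feature_cols) != self.n_features:
            raise ValueError("feature_cols length must equal n_features")

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (self.id_col, *self.feature_cols, self.stage_col,
                self.center_col, self.time_col, self.event_col,
                self.split_col)


@dataclass
class CohortTable:
    """A validated patient table plus its schema.

    Provides array views used by the modeling code; the underlying
    DataFrame keeps row order and patient identifiers.
    """

    df: pd.DataFrame
    schema: CohortSchema = field(default_factory=CohortSchema)

    def __post_init__(self):
        self.validate()

    # -- array views -------------------------------------------------
    @property
    def features(self) -> np.ndarray:
        return self.df[list(self.schema.feature_cols)].to_numpy(dtype=float)

    @property
    def time(self) -> np.ndarray:
        return self.df[self.schema.time_col].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.df[self.schema.event_col].to_numpy(dtype=int)

    @property
    def stage(self) -> np.ndarray:
        return self.df[self.schema.stage_col].to_numpy(dtype=int)

    @property
    def center(self) -> np.ndarray:
        return self.df[self.schema.center_col].to_numpy(dtype=object)

    @property
    def split(self) -> np.ndarray:
        return self.df[self.schema.split_col].to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask_or_split) -> "CohortTable":
        """Rows matching a boolean mask or a split label."""
        if isinstance(mask_or_split, str):
            mask = self.split == mask_or_split
        else:
            mask = np.asarray(mask_or_split)
        sub = self.df.loc[mask].reset_index(drop=True)
        return CohortTable(sub, self.schema)

    def validate(self) -> None:
        s = self.schema
        errors: list[str] = []
        missing = [c for c in s.required_columns if c not in self.df.columns]
        if missing:
            raise CohortValidationError(
                [f"missing column(s): {', '.join(missing)}"])

        for col in (*s.feature_cols, s.time_col, s.event_col, s.stage_col):
            coerced = pd.to_numeric(self.df[col], errors="coerce")
            bad = self.df.index[coerced.isna()].tolist()
            if bad:
                errors.append(f"non-numeric or missing {col!r} in rows {bad}")
            else:
                self.df[col] = coerced
        na_rows = self.df.index[
            self.df[list(s.required_columns)].isna().any(axis=1)].tolist()
        if na_rows:
            errors.append(f"missing values in rows {na_rows}")
        if errors:
            raise CohortValidationError(errors)

        t = self.df[s.time_col]
        bad = self.df.index[~(t > 0)].tolist()
        if bad:
            errors.append(f"non-positive time in rows {bad}")
        e = self.df[s.event_col]
        bad = self.df.index[~e.isin([0, 1])].tolist()
        if bad:
            errors.append(f"event not in {{0,1}} in rows {bad}")
        st = self.df[s.stage_col]
        bad = self.df.index[~st.isin(list(s.stages))].tolist()
        if bad:
            errors.append(f"stage outside {s.stages} in rows {bad}")
        if s.centers is not None:
            bad = self.df.index[
                ~self.df[s.center_col].astype(str).isin(
                    [str(c) for c in s.centers])].tolist()
            if bad:
                errors.append(f"unknown center label in rows {bad}")
        bad = self.df.index[
            ~self.df[s.split_col].astype(str).isin(SPLITS)].tolist()
        if bad:
            errors.append(f"unknown split label in rows {bad}")
        if errors:
            raise CohortValidationError(errors)
        self.df[s.event_col] = self.df[s.event_col].astype(int)
        self.df[s.stage_col] = self.df[s.stage_col].astype(int)


def read_cohort(path: str | Path, schema: CohortSchema | None = None
                ) -> CohortTable:
    """Read and validate a cohort CSV/TSV (delimiter chosen by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return CohortTable(df, schema or CohortSchema())


def write_cohort(table: CohortTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Training configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Hyperparameters shared across the three model components.

    ``k_u`` is the number of discrete latent classes; ``beta_*`` weight the
    reconstruction, concept, proxy, and KL terms of the autoencoder loss.
    The Gumbel-softmax temperature is annealed exponentially from
    ``temperature_start`` to ``temperature_end`` over ``anneal_steps``
    gradient steps.
    """

    k_u: int = 10
    beta_x: float = 1.0
    beta_c: float = 1.0
    beta_w: float = 1.0
    beta_kl: float = 1.0
    temperature_start: float = 1.0
    temperature_end: float = 0.1
    anneal_steps: int = 1000
    batch_size: int = 256
    learning_rate: float = 0.01
    optimizer: str = "adam"
    max_epochs: int = 200
    early_stopping_patience: int = 10
    seed: int = 0
    epsilon_prevalence: float = 1e-6
    normalize_adjusted_posterior: bool = False
    kld_mode: str = "batch_mean"          # or "per_sample"
    straight_through: bool = False
    estimator_hidden: tuple[int, ...] = (32, 32)
    hazard_hidden: tuple[int, ...] = (32, 32)
    posterior_mode: str = "sigmoid"       # or "softmax"
    prevalence_mode: str = "soft"         # or "hard"
    finetune_lr_factor: float = 0.1
    weight_decay: float = 1e-3            # L2 on hazard-net weights
    dropout: float = 0.2                  # hazard-net hidden layers
    horizon_months: float = 60.0

    def __post_init__(self):
        if self.k_u < 1:
            raise ValueError("k_u must be >= 1")
        for name in ("beta_x", "beta_c", "beta_w", "beta_kl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (self.temperature_start >= self.temperature_end > 0):
            raise ValueError(
                "require temperature_start >= temperature_end > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.kld_mode not in ("batch_mean", "per_sample"):
            raise ValueError("kld_mode must be 'batch_mean' or 'per_sample'")
        if self.posterior_mode not in ("sigmoid", "softmax"):
            raise ValueError("posterior_mode must be 'sigmoid' or 'softmax'")
        if isinstance(self.estimator_hidden, list):
            self.estimator_hidden = tuple(self.estimator_hidden)
        if isinstance(self.hazard_hidden, list):
            self.hazard_hidden = tuple(self.hazard_hidden)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown training config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["estimator_hidden"] = list(self.estimator_hidden)
        d["hazard_hidden"] = list(self.hazard_hidden)
        return d


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# Evaluation report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-site and overall discrimination results for one model."""

    model_id: str
    seed: int
    overall: dict                        # {"cindex", "lower", "upper", "n"}
    per_site: dict = field(default_factory=dict)   # site -> same shape
    auc_months: list = field(default_factory=list)
    auc_values: list = field(default_factory=list)  # None where undefined
    logrank: dict = field(default_factory=dict)     # site -> {stat, p}
    reference_site: str | None = None
    disparity: float | None = None

    def __post_init__(self):
        for d in (self.overall, *self.per_site.values()):
            c = d["cindex"]
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"C-index {c} outside [0, 1]")
            if not (d["lower"] <= c <= d["upper"]):
                raise ValueError("CI must bracket the point estimate")
        for a in self.auc_values:
            if a is not None and not (0.0 <= a <= 1.0):
                raise ValueError(f"AUC {a} outside [0, 1]")
        if len(self.auc_months) != len(self.auc_values):
            raise ValueError("AUC series length mismatch")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(**d)


def write_report(report: EvalReport, path: str | Path) -> None:
    """Write an EvalReport as JSON plus a flat CSV next to it."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    rows = [{"site": "overall", **report.overall}]
    rows += [{"site": site, **vals} for site, vals in report.per_site.items()]
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)


def read_report(path: str | Path) -> EvalReport:
    with open(path) as fh:
        return EvalReport.from_dict(json.load(fh))
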