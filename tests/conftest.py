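import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import causalsurv as cs

settings.register_profile(
    "ci", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_cohort_df(n=20, seed=0, n_centers=2, split="internal-train"):
    """Small schema-valid cohort with random but reproducible content."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)]})
    for j in range(15):
        df[f"feat_{j + 1}"] = rng.uniform(0, 100, n).round(3)
    df["stage"] = rng.integers(1, 4, n)
    df["center"] = rng.choice([f"site{c}" for c in range(n_centers)], n)
    df["time"] = rng.uniform(1, 60, n).round(3)
    df["event"] = rng.integers(0, 2, n)
    df["split"] = split
    return df


@pytest.fixture
def cohort_df():
    return make_cohort_df()


@pytest.fixture
def cohort(cohort_df):
    return cs.CohortTable(cohort_df)


@pytest.fixture(scope="session")
def separable_sim():
    """Well-separated two-class cohorts with ground truth, shared across
    tests that need a recoverable latent structure."""
    cfg = cs.two_class_shift_config(seed=11, n_P=3000, n_Q=1500,
                                    separation=6.0)
    return cfg, cs.simulate_domain(cfg, "P"), cs.simulate_domain(cfg, "Q")


@pytest.fixture(scope="session")
def trained_ae(separable_sim):
    cfg, sim_p, _ = separable_sim
    tc = cs.TrainingConfig(k_u=2, seed=11, max_epochs=60)
    train = sim_p.table.subset("internal-train")
    val = sim_p.table.subset("internal-val")
    return tc, cs.train_autoencoder(train, tc, val_cohort=val)


@pytest.fixture(scope="session")
def trained_estimator(separable_sim, trained_ae):
    _, sim_p, _ = separable_sim
    tc, ae = trained_ae
    est = cs.train_estimator(sim_p.table.subset("internal-train"), ae, tc)
    return tc, ae, est
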