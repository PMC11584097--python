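"""Plotting helpers: AUC-over-time curves and per-site Kaplan-Meier."""

from __future__ import annotations

import numpy as np

from .io_tables import CohortTable, EvalReport


def plot_auc_over_time(reports: dict[str, EvalReport], path) -> None:
    """One AUC-versus-month line per model; missing months are gaps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, rep in reports.items():
        months = np.asarray(rep.auc_months, dtype=float)
        values = np.array([np.nan if v is None else v
                           for v in rep.auc_values])
        ax.plot(months, values, label=name)
    ax.set_xlabel("months")
    ax.set_ylabel("cumulative/dynamic AUC")
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_km_by_site(cohort: CohortTable, path) -> None:
    """Kaplan-Meier recurrence-free survival curve per site."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(7, 4))
    centers = np.array([str(c) for c in cohort.center])
    for site in np.unique(centers):
        mask = centers == site
        if mask.sum() < 2:
            continue
        km = KaplanMeierFitter()
        km.fit(cohort.time[mask], cohort.event[mask], label=site)
        km.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("months")
    ax.set_ylabel("recurrence-free survival")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
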