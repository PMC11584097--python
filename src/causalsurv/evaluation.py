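"""Discrimination metrics and multi-site evaluation.

Harrell's concordance index (optionally at an administrative horizon),
cumulative/dynamic AUC over a month grid, percentile bootstrap confidence
intervals with a shared resampling seed so competing models are scored on
identical resamples, the two-group log-rank test, and a per-site report
with a disparity summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, rankdata

from .io_tables import CohortTable, EvalReport

__all__ = [
    "BootstrapSpec",
    "concordance_index",
    "auc_over_time",
    "bootstrap_ci",
    "logrank_test",
    "site_report",
]


@dataclass
class BootstrapSpec:
    n_iterations: int = 100
    ci_level: float = 0.95
    seed: int = 0
    method: str = "bootstrap"        # or "subsample" (without replacement)
    subsample_fraction: float = 0.8

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")


def _apply_horizon(times, events, horizon):
    if horizon is None:
        return times, events
    t = np.minimum(times, horizon)
    e = np.where(times <= horizon, events, 0)
    return t, e


def concordance_index(times, events, risks, horizon=None) -> float:
    """Harrell's C over admissible pairs; tied risks count one half.

    A pair (i, j) is admissible when i's event is observed strictly
    before j's time, or at the same recorded time when j is censored.
    ``horizon`` first censors administratively at that month.  With no
    admissible pairs the conventional 0.5 is returned with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risks = np.asarray(risks, dtype=float)
    if not (len(times) == len(events) == len(risks)):
        raise ValueError("times, events, risks must share length")
    times, events = _apply_horizon(times, events, horizon)
    if events.sum() == 0:
        warnings.warn("all observations censored; C-index undefined, "
                      "returning 0.5")
        return 0.5

    # pairwise, chunked over event rows to bound memory
    ev_idx = np.where(events == 1)[0]
    num = 0.0
    n_pairs = 0
    chunk = 512
    for start in range(0, len(ev_idx), chunk):
        rows = ev_idx[start:start + chunk]
        ti = times[rows][:, None]
        ri = risks[rows][:, None]
        earlier = ti < times[None, :]
        tied_time = (ti == times[None, :]) & (events[None, :] == 0)
        admissible = earlier | tied_time
        # exclude self-pairs (self is never admissible: same time, event=1)
        conc = admissible & (ri > risks[None, :])
        ties = admissible & (ri == risks[None, :])
        num += conc.sum() + 0.5 * ties.sum()
        n_pairs += admissible.sum()
    if n_pairs == 0:
        warnings.warn("no admissible pairs; returning 0.5")
        return 0.5
    return float(num / n_pairs)


def auc_over_time(times, events, risks,
                  month_grid=None) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative/dynamic AUC at each grid month (default 2..58).

    At month t, cases are patients with an observed event by t and
    controls those still at risk beyond t; patients censored by t are
    excluded.  Months with no cases or no controls yield NaN, preserving
    the grid length.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risks = np.asarray(risks, dtype=float)
    if month_grid is None:
        month_grid = np.arange(2, 59)
    month_grid = np.asarray(month_grid, dtype=float)
    if month_grid.size == 0:
        raise ValueError("month grid is empty")
    out = np.full(len(month_grid), np.nan)
    for i, t in enumerate(month_grid):
        cases = (times <= t) & (events == 1)
        controls = times > t
        n1, n0 = int(cases.sum()), int(controls.sum())
        if n1 == 0 or n0 == 0:
            continue
        pooled = np.concatenate([risks[cases], risks[controls]])
        ranks = rankdata(pooled)
        out[i] = (ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return month_grid, out


def resample_indices(n: int, spec: BootstrapSpec) -> np.ndarray:
    """The (n_iterations, m) resample index matrix implied by a spec.

    Depends only on the spec and n, never on the metric or model, which
    is what makes bootstrap comparisons across models paired.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.method == "subsample":
        m = max(int(round(spec.subsample_fraction * n)), 1)
        return np.stack([rng.permutation(n)[:m]
                         for _ in range(spec.n_iterations)])
    return rng.integers(0, n, size=(spec.n_iterations, n))


def bootstrap_ci(metric_fn, data: tuple, spec: BootstrapSpec
                 ) -> tuple[float, float, float]:
    """Percentile bootstrap CI of ``metric_fn(*data)`` over row resamples.

    ``data`` is a tuple of equal-length arrays resampled jointly.  The
    point estimate is the metric on the full data; iterations where the
    metric is undefined (NaN or raising ValueError) are dropped with a
    warning.
    """
    data = tuple(np.asarray(a) for a in data)
    n = len(data[0])
    if n == 0:
        raise ValueError("data is empty")
    point = float(metric_fn(*data))
    idx_matrix = resample_indices(n, spec)
    values = []
    n_missing = 0
    for idx in idx_matrix:
        resampled = tuple(a[idx] for a in data)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = float(metric_fn(*resampled))
        except ValueError:
            v = np.nan
        if np.isnan(v):
            n_missing += 1
        else:
            values.append(v)
    if n_missing:
        warnings.warn(f"metric undefined on {n_missing} bootstrap "
                      "iteration(s); CI computed over the rest")
    if not values:
        return point, np.nan, np.nan
    alpha = 1.0 - spec.ci_level
    lower = float(np.percentile(values, 100 * alpha / 2))
    upper = float(np.percentile(values, 100 * (1 - alpha / 2)))
    return point, lower, upper


def logrank_test(times_a, events_a, times_b, events_b
                 ) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic (1 df) and p-value."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be nonempty")
    if events_a.sum() + events_b.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined")
        return 0.0, 1.0
    event_times = np.unique(np.concatenate(
        [times_a[events_a == 1], times_b[events_b == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = int((times_a >= t).sum())
        n_b = int((times_b >= t).sum())
        d_a = int(((times_a == t) & (events_a == 1)).sum())
        d_b = int(((times_b == t) & (events_b == 1)).sum())
        n = n_a + n_b
        d = d_a + d_b
        if n < 2:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        var += d * (n_a / n) * (n_b / n) * (n - d) / max(n - 1, 1)
    if var <= 0:
        warnings.warn("zero log-rank variance")
        return 0.0, 1.0
    stat = o_minus_e ** 2 / var
    return float(stat), float(chi2.sf(stat, df=1))


def site_report(model_scores: dict[str, np.ndarray], cohort: CohortTable,
                spec: BootstrapSpec, horizon: float | None = 60.0,
                reference_site: str | None = None,
                month_grid=None, seed: int | None = None
                ) -> dict[str, EvalReport]:
    """Overall and per-site C-index (with CIs), AUC series, and log-rank
    comparisons against a reference site, for each model's risk scores.

    ``model_scores`` maps model identifiers to per-patient risk scores
    aligned with the cohort rows.  The reference site defaults to the
    largest site; sites with fewer than two rows are skipped.  The
    disparity summary is max minus min per-site C-index.
    """
    times, events = cohort.time, cohort.event
    centers = np.array([str(c) for c in cohort.center])
    site_names, site_counts = np.unique(centers, return_counts=True)
    if reference_site is None:
        reference_site = site_names[np.argmax(site_counts)]

    logrank = {}
    ref_mask = centers == reference_site
    for site in site_names:
        if site == reference_site:
            continue
        m = centers == site
        stat, p = logrank_test(times[m], events[m],
                               times[ref_mask], events[ref_mask])
        logrank[site] = {"stat": stat, "p": p}

    def cfun(t, e, r):
        return concordance_index(t, e, r, horizon=horizon)

    reports = {}
    for name, scores in model_scores.items():
        scores = np.asarray(scores, dtype=float)
        point, lo, hi = bootstrap_ci(cfun, (times, events, scores), spec)
        overall = {"cindex": point, "lower": min(lo, point),
                   "upper": max(hi, point), "n": int(len(cohort))}
        per_site = {}
        for site, count in zip(site_names, site_counts):
            if count < 2:
                warnings.warn(f"site {site!r} has fewer than 2 rows; skipped")
                continue
            m = centers == site
            p_, l_, h_ = bootstrap_ci(
                cfun, (times[m], events[m], scores[m]), spec)
            per_site[site] = {"cindex": p_, "lower": min(l_, p_),
                              "upper": max(h_, p_), "n": int(count)}
        grid, aucs = auc_over_time(times, events, scores, month_grid)
        cvals = [v["cindex"] for v in per_site.values()]
        disparity = float(max(cvals) - min(cvals)) if cvals else 0.0
        reports[name] = EvalReport(
            model_id=name, seed=seed if seed is not None else spec.seed,
            overall=overall, per_site=per_site,
            auc_months=grid.tolist(),
            auc_values=[None if np.isnan(v) else float(v) for v in aucs],
            logrank=logrank, reference_site=str(reference_site),
            disparity=disparity)
    return reports
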