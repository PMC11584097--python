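"""Independent brute-force oracles used to validate the implementation.

Everything here is written as plain loops over definitions, deliberately
avoiding the package's own vectorized code paths.
"""

import math

import numpy as np


def cindex_bruteforce(times, events, risks, horizon=None):
    """Harrell's C by explicit enumeration of all ordered pairs."""
    times = list(map(float, times))
    events = list(map(int, events))
    risks = list(map(float, risks))
    if horizon is not None:
        events = [e if t <= horizon else 0 for t, e in zip(times, events)]
        times = [min(t, horizon) for t in times]
    num = 0.0
    pairs = 0
    n = len(times)
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if i == j:
                continue
            admissible = (times[i] < times[j]) or (
                times[i] == times[j] and events[j] == 0)
            if not admissible:
                continue
            pairs += 1
            if risks[i] > risks[j]:
                num += 1.0
            elif risks[i] == risks[j]:
                num += 0.5
    if pairs == 0:
        return 0.5
    return num / pairs


def binary_auc_bruteforce(labels, scores):
    """Mann-Whitney AUC by pair enumeration (1 = case)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        return float("nan")
    num = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                num += 1.0
            elif p == q:
                num += 0.5
    return num / (len(pos) * len(neg))


def mse_scalar(x, x_hat):
    total = 0.0
    count = 0
    for row, row_hat in zip(x, x_hat):
        for a, b in zip(row, row_hat):
            total += (a - b) ** 2
            count += 1
    return total / count


def cross_entropy_scalar(logits, labels):
    total = 0.0
    for row, lab in zip(logits, labels):
        m = max(row)
        lse = m + math.log(sum(math.exp(v - m) for v in row))
        total += lse - row[lab]
    return total / len(labels)


def kl_uniform_scalar(p, k):
    total = 0.0
    for v in p:
        if v > 0:
            total += v * math.log(v * k)
    return total


def cox_nll_bruteforce(eta, times, events):
    """Mean (per event) negative log partial likelihood, Breslow ties."""
    n = len(times)
    total = 0.0
    n_events = sum(events)
    for i in range(n):
        if events[i] != 1:
            continue
        denom = sum(math.exp(eta[j]) for j in range(n)
                    if times[j] >= times[i])
        total -= eta[i] - math.log(denom)
    return total / n_events


def breslow_bruteforce(times, events, eta, t_eval):
    """Baseline cumulative hazard at a single time point."""
    event_times = sorted({times[i] for i in range(len(times))
                          if events[i] == 1 and times[i] <= t_eval})
    h = 0.0
    for t in event_times:
        d = sum(1 for i in range(len(times))
                if times[i] == t and events[i] == 1)
        denom = sum(math.exp(eta[i]) for i in range(len(times))
                    if times[i] >= t)
        h += d / denom
    return h


def cox_newton_fit(x, times, events, n_iter=60):
    """Maximum partial likelihood for a linear Cox model by Newton's
    method with explicit loops (small problems only)."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    beta = np.zeros(p)
    for _ in range(n_iter):
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for i in range(n):
            if events[i] != 1:
                continue
            risk_set = [j for j in range(n) if times[j] >= times[i]]
            w = np.array([math.exp(x[j] @ beta) for j in risk_set])
            w = w / w.sum()
            xbar = sum(wj * x[j] for wj, j in zip(w, risk_set))
            grad += x[i] - xbar
            outer = sum(wj * np.outer(x[j], x[j])
                        for wj, j in zip(w, risk_set))
            hess -= outer - np.outer(xbar, xbar)
        step = np.linalg.solve(hess - 1e-10 * np.eye(p), grad)
        beta = beta - step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta
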