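"""Independent reference implementations used to certify the package.

Everything here is deliberately written without using cohortmsm
internals: a truncated-series (uniformization) matrix exponential, the
closed-form transition probabilities of small progressive chains, a
direct-product panel likelihood for the two-state model, and a
grid-search maximizer.
"""

from __future__ import annotations

import math

import numpy as np


def expm_series(q: np.ndarray, t: float, tol: float = 1e-16, max_terms: int = 100000) -> np.ndarray:
    """exp(Q t) by uniformization: sum_n Poisson(n; c t) (I + Q/c)^n."""
    q = np.asarray(q, dtype=float)
    k = q.shape[0]
    c = float(-q.diagonal().min())
    if c <= 0:
        return np.eye(k)
    m = np.eye(k) + q / c
    x = c * t
    w = math.exp(-x)
    term = np.eye(k)
    out = w * term
    total = w
    n = 0
    while 1.0 - total > tol and n < max_terms:
        n += 1
        term = term @ m
        w = w * x / n
        out = out + w * term
        total += w
    return out


def random_generator(rng: np.random.Generator, n_states: int, max_rate: float = 2.0) -> np.ndarray:
    """Random dense generator with off-diagonal rates in [0, max_rate]."""
    q = rng.uniform(0.0, max_rate, size=(n_states, n_states))
    np.fill_diagonal(q, 0.0)
    # knock out a few transitions to vary the sparsity pattern
    q[rng.uniform(size=q.shape) < 0.3] = 0.0
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def two_state_p01(lam: float, t: float) -> float:
    """P(absorbed by t) for the 0 -> 1 chain with constant rate lam."""
    return 1.0 - math.exp(-lam * t)


def progressive3_probs(a: float, b: float, t: float) -> tuple[float, float, float]:
    """Closed-form occupancy of the 0 -> 1 -> 2 chain (rates a then b) at t."""
    p00 = math.exp(-a * t)
    if abs(a - b) > 1e-12:
        p01 = a / (b - a) * (math.exp(-a * t) - math.exp(-b * t))
    else:
        p01 = a * t * math.exp(-a * t)
    return p00, p01, 1.0 - p00 - p01


def two_state_panel_loglik(frame, lam: float) -> float:
    """Direct-product panel log-likelihood for the two-state chain."""
    ll = 0.0
    for _, g in frame.sort_values(["subject_id", "time"]).groupby("subject_id"):
        times = g["time"].to_numpy()
        states = g["state"].to_numpy()
        for j in range(1, len(g)):
            dt = times[j] - times[j - 1]
            if states[j - 1] == 0 and states[j] == 0:
                ll += -lam * dt
            elif states[j - 1] == 0 and states[j] == 1:
                ll += math.log(1.0 - math.exp(-lam * dt))
            elif states[j - 1] == 1 and states[j] == 1:
                ll += 0.0
            else:
                return -math.inf
    return ll


def grid_mle_two_state(frame, lo: float = 1e-4, hi: float = 2.0, rounds: int = 6, points: int = 201) -> float:
    """Grid search + refinement for the two-state panel MLE of lam."""
    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        lls = np.array([two_state_panel_loglik(frame, lam) for lam in grid])
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, points - 1)]
    return float(grid[i])
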