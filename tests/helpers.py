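"""Independent oracles used by the test suite (kept free of package internals)."""
from __future__ import annotations

import itertools

import numpy as np


def brute_force_embed_count(seg_lengths, E, tau, tp):
    """Enumerate valid (delay vector, target) pairs the slow, obvious way."""
    count = 0
    for L in seg_lengths:
        for t in range(L):
            lags_ok = all(0 <= t - k * tau < L for k in range(E))
            target_ok = 0 <= t + tp < L
            if lags_ok and target_ok:
                count += 1
    return count


def plugin_te(effect_states, cause_states, n_states=3):
    """Histogram plug-in transfer entropy cause -> effect on discrete chains.

    TE = I(x_{t+1}; y_t | x_t) estimated from empirical trigram frequencies.
    """
    x = np.asarray(effect_states, dtype=int)
    y = np.asarray(cause_states, dtype=int)
    n = len(x) - 1
    joint = np.zeros((n_states, n_states, n_states))  # x_{t+1}, x_t, y_t
    for t in range(n):
        joint[x[t + 1], x[t], y[t]] += 1
    joint /= joint.sum()
    p_xx = joint.sum(axis=2)          # x_{t+1}, x_t
    p_x = joint.sum(axis=(0, 2))      # x_t
    p_xy = joint.sum(axis=0)          # x_t, y_t
    te = 0.0
    for a, b, c in itertools.product(range(n_states), repeat=3):
        p = joint[a, b, c]
        if p > 0:
            num = p * p_x[b]
            den = p_xx[a, b] * p_xy[b, c]
            te += p * np.log(num / den)
    return te


def weighted_ridge_oracle(X, y, w, lam):
    """Dense solve of the locally weighted ridge problem (intercept unpenalized)."""
    Xa = np.column_stack([np.ones(len(y)), X])
    P = np.eye(Xa.shape[1])
    P[0, 0] = 0.0
    G = (Xa * w[:, None]).T @ Xa + lam * P
    return np.linalg.solve(G, (Xa * w[:, None]).T @ y)


def discretize(series, n_states=3):
    """Equal-frequency discretization to integer states."""
    qs = np.quantile(series, np.linspace(0, 1, n_states + 1)[1:-1])
    return np.digitize(series, qs)
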