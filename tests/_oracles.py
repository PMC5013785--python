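"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (brute-force
grids, closed forms, exhaustive enumeration) and stays independent of the
package's own code paths so it can serve as a cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def gaussian(x, center, sigma):
    return math.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def grid_best_objective(X, y, cs_plus, cs_minus, lo=0.05, hi=10.0, step=0.01):
    """Exhaustive grid search of the joint least-squares objective.

    Evaluates the eight-point objective on the full (sigma, sigma') grid and
    returns the smallest value found. Fully vectorised; the multiplicative
    interaction only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = X[:, 0]
    is_diff = X[:, 1] > 0.5
    sig = np.arange(lo + step, hi + step / 2, step)  # open lower bound

    pos_abs, y_abs = pos[~is_diff], y[~is_diff]
    pos_diff, y_diff = pos[is_diff], y[is_diff]

    G_abs = np.exp(-((pos_abs[None, :] - cs_plus) ** 2) / (2 * sig[:, None] ** 2))
    obj_abs = np.sum((y_abs[None, :] - 100.0 * G_abs) ** 2, axis=1)  # (S,)

    G_diff = np.exp(-((pos_diff[None, :] - cs_plus) ** 2) / (2 * sig[:, None] ** 2))  # (S, nd)
    Gp_diff = np.exp(-((pos_diff[None, :] - cs_minus) ** 2) / (2 * sig[:, None] ** 2))  # (S, nd)

    best = math.inf
    chunk = 200
    for start in range(0, len(sig), chunk):
        Gi = G_diff[start:start + chunk]  # (c, nd)
        pred = 100.0 * Gi[:, None, :] * (1.0 - Gp_diff[None, :, :])  # (c, S, nd)
        obj = np.sum((y_diff[None, None, :] - pred) ** 2, axis=2)  # (c, S)
        total = obj + obj_abs[start:start + chunk, None]
        best = min(best, float(total.min()))
    return best


def grid_peak(model_response, center_plus, window=4.0, step=0.001):
    """Brute-force argmax of a response callable on a dense grid."""
    grid = np.arange(center_plus - window, center_plus + window + step / 2, step)
    values = np.asarray([model_response(x) for x in grid])
    return float(grid[int(np.argmax(values))])


def cochran_q_by_hand(matrix):
    """Cochran's Q from explicit loops over the closed form."""
    matrix = [list(row) for row in matrix]
    n, k = len(matrix), len(matrix[0])
    col = [sum(matrix[i][j] for i in range(n)) for j in range(k)]
    row = [sum(matrix[i]) for i in range(n)]
    total = sum(row)
    num = k * (k - 1) * sum((c - total / k) ** 2 for c in col)
    den = k * sum(row) - sum(r**2 for r in row)
    return num / den


def fisher_two_sided_by_enumeration(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def holm_by_hand(p_values):
    """Holm step-down executed literally: sort, scale, monotonise, cap."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m - rank) * p_values[idx])
        running = max(running, value)
        adjusted[idx] = running
    return adjusted
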