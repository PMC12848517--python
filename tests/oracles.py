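"""Independent oracles used by the test suite.

Deliberately naive implementations (dense matrices, explicit loops) that do
not share code paths with the package: a brute-force profiled-REML criterion,
a hand-executed Benjamini-Hochberg step-up, and the closed-form noncentral-t
power of a fixed-effects contrast.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def reml_criterion_direct(y, X, litter_index, lam):
    """Profiled -2 REML log-likelihood at variance ratio lam, dense formula."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    n_litters = int(litter_index.max()) + 1
    Z = np.zeros((n, n_litters))
    Z[np.arange(n), litter_index] = 1.0
    H = np.eye(n) + lam * Z @ Z.T
    Hinv = np.linalg.inv(H)
    A = X.T @ Hinv @ X
    beta = np.linalg.solve(A, X.T @ Hinv @ y)
    r = y - X @ beta
    rss = float(r @ Hinv @ r)
    return (
        (n - p) * np.log(rss / (n - p))
        + np.linalg.slogdet(H)[1]
        + np.linalg.slogdet(A)[1]
    )


def reml_grid_search(y, X, litter_index, n_grid=10_000):
    """Exhaustive lambda-grid minimizer of the REML criterion.

    Returns (lam_best, crit_best, grid).  The grid spans lambda = 0 and a
    geometric range 1e-6..1e4.
    """
    grid = np.concatenate([[0.0], np.geomspace(1e-6, 1e4, n_grid - 1)])
    crits = np.array([reml_criterion_direct(y, X, litter_index, lam) for lam in grid])
    k = int(np.argmin(crits))
    return float(grid[k]), float(crits[k]), grid


def bh_stepup(pvalues):
    """Hand-executed Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def fixed_effects_power(effect, sigma, X, contrast, alpha):
    """Two-sided noncentral-t power of c'beta in a pure fixed-effects model."""
    X = np.asarray(X, float)
    c = np.asarray(contrast, float)
    n, p = X.shape
    se = sigma * np.sqrt(c @ np.linalg.inv(X.T @ X) @ c)
    ncp = effect / se
    df = n - p
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def mc_band(p, n_iter, k=3.0):
    """k Monte-Carlo standard errors of a binomial proportion estimate."""
    return k * np.sqrt(p * (1.0 - p) / n_iter)
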