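"""Independent brute-force oracles used by the test suite.

The REML oracle maximises the restricted log-likelihood by iterative grid
refinement over (beta, tau2) directly — no quasi-Newton steps, no code shared
with the fitting path — for intercept-only models with one random level and
diagonal sampling variances.
"""

from __future__ import annotations

import numpy as np


def reml_objective(beta: float, tau2: float, y, v, groups) -> float:
    """Restricted log-likelihood at (beta, tau2), up to an additive constant."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    g = np.asarray(groups)
    sigma = np.diag(v) + tau2 * (g[:, None] == g[None, :])
    sign, ld1 = np.linalg.slogdet(sigma)
    if sign <= 0:
        return -np.inf
    si = np.linalg.inv(sigma)
    x = np.ones(len(y))
    xsx = float(x @ si @ x)
    r = y - beta
    return -0.5 * (ld1 + np.log(xsx) + float(r @ si @ r))


def grid_search_reml(y, v, groups, n_rounds: int = 14) -> tuple[float, float]:
    """Exhaustive grid search with iterative refinement; returns (beta, tau2)."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    g = np.asarray(groups)
    same = (g[:, None] == g[None, :]).astype(float)
    ones = np.ones(len(y))

    b_lo, b_hi = float(y.min() - 2.0), float(y.max() + 2.0)
    t_lo, t_hi = 0.0, float(10.0 * max(y.var(), v.mean(), 0.1))
    best_b = best_t = 0.0
    for _ in range(n_rounds):
        bs = np.linspace(b_lo, b_hi, 21)
        ts = np.linspace(t_lo, t_hi, 21)
        best_val = -np.inf
        for t in ts:
            sigma = np.diag(v) + t * same
            sign, ld1 = np.linalg.slogdet(sigma)
            if sign <= 0:
                continue
            si = np.linalg.inv(sigma)
            xsx = float(ones @ si @ ones)
            # quadratic form for every beta on the grid at once
            r = y[None, :] - bs[:, None]
            quad = np.einsum("bi,ij,bj->b", r, si, r)
            vals = -0.5 * (ld1 + np.log(xsx) + quad)
            j = int(np.argmax(vals))
            if vals[j] > best_val:
                best_val, best_b, best_t = float(vals[j]), float(bs[j]), float(t)
        b_step = (b_hi - b_lo) / 20.0
        t_step = (t_hi - t_lo) / 20.0
        b_lo, b_hi = best_b - 1.5 * b_step, best_b + 1.5 * b_step
        t_lo, t_hi = max(best_t - 1.5 * t_step, 0.0), best_t + 1.5 * t_step
    return best_b, best_t


def random_instance(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A small random meta-analytic instance: k <= 6 effects, one grouping."""
    k = int(rng.integers(3, 7))
    n_groups = int(rng.integers(2, k + 1))
    # at least two realised groups: with a single group (and an intercept) the
    # REML profile is exactly flat in tau2 (unidentifiable by construction)
    groups = np.concatenate([[0, 1], rng.integers(0, n_groups, size=k - 2)])
    v = rng.uniform(0.03, 0.4, size=k)
    tau = rng.uniform(0.0, 1.0)
    mu = rng.normal(0.0, 1.0)
    u = rng.normal(0.0, tau, size=n_groups)
    y = mu + u[groups] + rng.normal(0.0, np.sqrt(v))
    return y, v, groups
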