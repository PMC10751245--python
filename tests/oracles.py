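"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route unrelated to the package's
implementation: direct numerical likelihood maximisation for the bulk-trend
GLM, and exhaustive pairwise application of the multiple-range rule for
Duncan letter grouping.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import expit
from scipy.stats import studentized_range

_X = np.array([0.0, 1.0, 2.0])


def binomial_nll(theta, alt, depth):
    """Negative binomial log-likelihood of the logistic bulk trend."""
    eta = theta[0] + theta[1] * _X
    mu = np.clip(expit(eta), 1e-14, 1 - 1e-14)
    return -(alt * np.log(mu) + (depth - alt) * np.log(1 - mu)).sum()


def _num_grad_hess(f, x, h=1e-6):
    g = np.zeros(2)
    H = np.zeros((2, 2))
    I = np.eye(2)
    for i in range(2):
        g[i] = (f(x + h * I[i]) - f(x - h * I[i])) / (2 * h)
    for i in range(2):
        for j in range(2):
            H[i, j] = (
                f(x + h * I[i] + h * I[j])
                - f(x + h * I[i] - h * I[j])
                - f(x - h * I[i] + h * I[j])
                + f(x - h * I[i] - h * I[j])
            ) / (4 * h * h)
    return g, H


def glm_oracle(alt, depth):
    """(beta, se, stat) from a grid start plus Newton steps on numerically
    differentiated likelihood derivatives."""
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)

    def f(th):
        return binomial_nll(th, alt, depth)

    grid = np.linspace(-4, 4, 41)
    best = min(((f((a, b)), a, b) for a in grid for b in grid))
    x = np.array(best[1:], dtype=float)
    for _ in range(200):
        g, H = _num_grad_hess(f, x)
        step = np.linalg.solve(H, g)
        x = x - step
        if np.abs(step).max() < 1e-12:
            break
    # Richardson-extrapolated Hessian: (4 H(h/2) - H(h)) / 3 kills the O(h^2) term
    _, H1 = _num_grad_hess(f, x, h=4e-3)
    _, H2 = _num_grad_hess(f, x, h=2e-3)
    H = (4.0 * H2 - H1) / 3.0
    se = math.sqrt(np.linalg.inv(H)[1, 1])
    beta = float(x[1])
    return beta, se, (beta / se) ** 2


@lru_cache(maxsize=4096)
def _oracle_q(p: int, df: float, alpha: float) -> float:
    return float(studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df))


def duncan_pairwise_oracle(means, sizes, values_list, alpha=0.05):
    """Pairwise separability under the multiple-range rule, brute force.

    ``means``/``sizes`` must be in descending-mean order.  A pair (i, j) is
    NOT separable iff some stretch [a, b] containing it has range <= the
    critical range for its span (computed from the one-way ANOVA error mean
    square and the stretch's harmonic mean group size).  Returns a boolean
    matrix ``separable[i][j]``.
    """
    k = len(means)
    n_total = sum(sizes)
    df_err = n_total - k
    sse = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in values_list)
    mse = sse / df_err

    def crit(a, b):
        span = b - a + 1
        n_h = span / sum(1.0 / sizes[t] for t in range(a, b + 1))
        return _oracle_q(span, df_err, alpha) * math.sqrt(mse / n_h)

    nonsig = np.zeros((k, k), dtype=bool)
    for a in range(k):
        for b in range(a, k):
            if mse == 0.0:
                homog = means[a] == means[b]
            else:
                homog = a == b or (means[a] - means[b]) <= crit(a, b)
            if homog:
                nonsig[a : b + 1, a : b + 1] = True
    separable = ~nonsig
    np.fill_diagonal(separable, False)
    return separable
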