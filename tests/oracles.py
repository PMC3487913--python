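"""Independent brute-force oracles used to validate the optimizers.

These deliberately share no code with the package implementations: the
simplex oracle enumerates all candidate supports, the NNLS oracle all sign
patterns, and the scalar oracle minimizes one-dimensional subproblems on a
grid with refinement.
"""

from itertools import combinations

import numpy as np


def simplex_oracle(c: np.ndarray, alpha: float) -> np.ndarray:
    """Minimize 0.5||h - c||^2 over the alpha-simplex by support enumeration.

    For every non-empty support S the equality-constrained minimizer is
    h_S = c_S - mu with mu = (sum(c_S) - alpha)/|S|; keep the feasible
    candidates and return the one with the best objective.
    """
    c = np.asarray(c, dtype=float)
    d = c.size
    best, best_obj = None, np.inf
    for size in range(1, d + 1):
        for support in combinations(range(d), size):
            idx = list(support)
            mu = (c[idx].sum() - alpha) / size
            h = np.zeros(d)
            h[idx] = c[idx] - mu
            if np.any(h[idx] < -1e-12):
                continue
            h[idx] = np.maximum(h[idx], 0.0)
            obj = 0.5 * np.sum((h - c) ** 2)
            if obj < best_obj - 1e-15:
                best, best_obj = h, obj
    assert best is not None
    return best


def nnls_oracle(G: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Minimize 0.5 x^T G x - f^T x over x >= 0 by sign-pattern enumeration."""
    d = f.size
    best, best_obj = np.zeros(d), 0.0
    for size in range(1, d + 1):
        for support in combinations(range(d), size):
            idx = list(support)
            x_s = np.linalg.solve(G[np.ix_(idx, idx)], f[idx])
            if np.any(x_s < -1e-12):
                continue
            x = np.zeros(d)
            x[idx] = np.maximum(x_s, 0.0)
            obj = 0.5 * x @ G @ x - f @ x
            if obj < best_obj - 1e-15:
                best, best_obj = x, obj
    return best


def scalar_min_oracle(fun, lo: float, hi: float, coarse: int = 2001, refine: int = 60):
    """Minimize a scalar function on [lo, hi]: coarse grid + golden-section."""
    grid = np.linspace(lo, hi, coarse)
    vals = [fun(t) for t in grid]
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, coarse - 1)]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = b - phi * (b - a)
    x2 = a + phi * (b - a)
    f1, f2 = fun(x1), fun(x2)
    for _ in range(refine):
        if f1 < f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - phi * (b - a)
            f1 = fun(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + phi * (b - a)
            f2 = fun(x2)
    return 0.5 * (a + b)


def grid2_min_oracle(fun, lo, hi, coarse: int = 201, zoom: int = 6):
    """Minimize a bivariate function on a box by iterated grid refinement."""
    lo = np.array(lo, dtype=float)
    hi = np.array(hi, dtype=float)
    for _ in range(zoom):
        xs = np.linspace(lo[0], hi[0], coarse)
        ys = np.linspace(lo[1], hi[1], coarse)
        vals = np.array([[fun(np.array([x, y])) for y in ys] for x in xs])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        dx = (hi[0] - lo[0]) / (coarse - 1)
        dy = (hi[1] - lo[1]) / (coarse - 1)
        lo = np.array([max(lo[0], xs[i] - 2 * dx), max(lo[1], ys[j] - 2 * dy)])
        hi = np.array([xs[i] + 2 * dx, ys[j] + 2 * dy])
    return np.array([(lo[0] + hi[0]) / 2, (lo[1] + hi[1]) / 2])


def random_pd_matrix(rng: np.random.Generator, d: int) -> np.ndarray:
    """Random symmetric positive-definite matrix with moderate conditioning."""
    M = rng.standard_normal((d, d))
    return M @ M.T + d * np.eye(d) * 0.1
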