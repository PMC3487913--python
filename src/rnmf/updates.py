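"""Exact block updates for the mixing and component matrices.

Each update minimizes its block subproblem exactly, including a proximal
term ``tau * ||. - previous||^2`` that keeps the subproblem strictly convex;
this is what guarantees monotone descent of the global objective and
convergence to critical points.

Rank-one residual convention: ``R`` passed to the per-column updates is
``X - W A^T`` *with component l added back*, i.e. X minus all components
except the one being updated. The solver maintains R cumulatively and
:func:`refresh_residual` bounds floating-point drift.
"""

from __future__ import annotations

import numpy as np

from .model import pair_incidence
from .nnls import NormalEquations, fnnls_solve
from .simplex import project_simplex

__all__ = [
    "update_mixing_column",
    "update_component_l1",
    "update_component_tikhonov",
    "update_component_related",
    "refresh_residual",
]


def update_mixing_column(
    R: np.ndarray,
    w: np.ndarray,
    a_prev: np.ndarray,
    alpha: float,
    tau_a: float,
) -> np.ndarray:
    """Exact minimizer over Delta_alpha of ``||R - w a^T||_F^2 + tau_a ||a - a_prev||^2``.

    The quadratic form of this subproblem is ``(||w||^2 + tau_a) * I``
    (diagonal), so the minimizer is the Euclidean projection onto the
    alpha-simplex of ``c = (R^T w + tau_a a_prev) / (||w||^2 + tau_a)``.
    When the base vector ``w`` degenerates to zero the proximal term takes
    over and the update returns ``a_prev`` unchanged.
    """
    if tau_a <= 0:
        raise ValueError("tau_a must be strictly positive")
    w = np.asarray(w, dtype=float)
    a_prev = np.asarray(a_prev, dtype=float)
    if R.shape != (w.size, a_prev.size):
        raise ValueError(
            f"residual shape {R.shape} incompatible with w ({w.size}) and "
            f"a_prev ({a_prev.size})"
        )
    c = (R.T @ w + tau_a * a_prev) / (w @ w + tau_a)
    return project_simplex(c, alpha)


def update_component_l1(
    R: np.ndarray,
    a: np.ndarray,
    w_prev: np.ndarray,
    lam: float,
    tau_w: float,
) -> np.ndarray:
    """Exact minimizer over ``w >= 0`` of the l1-penalized column subproblem.

    Minimizes ``||R - w a^T||_F^2 + lam * sum(w) + tau_w * ||w - w_prev||^2``.
    The KKT conditions give the closed-form soft threshold

        w_i = max(0, (R a)_i + tau_w * w_prev_i - lam/2) / (||a||^2 + tau_w)

    The threshold is lam/2 (not lam) because the fit term carries no 1/2
    factor. The truncation produces exact zeros.
    """
    a = np.asarray(a, dtype=float)
    w_prev = np.asarray(w_prev, dtype=float)
    denom = a @ a + tau_w
    if denom <= 0:
        raise ValueError(
            "mixing column is zero and tau_w = 0: subproblem not strictly convex"
        )
    f = R @ a + tau_w * w_prev
    return np.maximum(0.0, f - 0.5 * lam) / denom


def update_component_tikhonov(
    R: np.ndarray,
    a: np.ndarray,
    w_prev: np.ndarray,
    lam: float,
    L: np.ndarray,
    tau_w: float,
) -> np.ndarray:
    """Exact minimizer over ``w >= 0`` of the Tikhonov column subproblem.

    Minimizes ``||R - w a^T||_F^2 + lam ||L w||^2 + tau_w ||w - w_prev||^2``,
    a non-negative least squares problem solved on its normal equations
    (no explicit Cholesky of the stacked system):

        G = (||a||^2 + tau_w) I + lam L^T L,   f = R a + tau_w w_prev.

    With ``L = I`` this reduces to the closed-form shrinkage
    ``w_i = max(0, f_i) / (||a||^2 + lam + tau_w)``; the general path
    reproduces it.
    """
    a = np.asarray(a, dtype=float)
    w_prev = np.asarray(w_prev, dtype=float)
    L = np.asarray(L, dtype=float)
    n = w_prev.size
    if L.shape != (n, n):
        raise ValueError(f"filter must be {n}x{n}, got {L.shape}")
    G = lam * (L.T @ L)
    G = 0.5 * (G + G.T)  # exact symmetry against rounding
    G[np.diag_indices(n)] += a @ a + tau_w
    f = R @ a + tau_w * w_prev
    return fnnls_solve(NormalEquations(G, f))


def update_component_related(
    X: np.ndarray,
    A: np.ndarray,
    W_prev: np.ndarray,
    lam: float,
    pairs,
    tau_w: float,
) -> np.ndarray:
    """Exact minimizer over ``W >= 0`` of the related-base-vector subproblem.

    Minimizes ``||X - W A^T||_F^2 + lam ||W B||_F^2 + tau_w ||W - W_prev||_F^2``
    where B is the signed incidence matrix of the pair set. The penalty
    couples columns of W, so W is treated as a single block — but the
    problem decouples over *rows*: every feature row solves an NNLS with
    the shared k x k Gram matrix

        G = A^T A + lam B B^T + tau_w I

    computed once per call.
    """
    A = np.asarray(A, dtype=float)
    W_prev = np.asarray(W_prev, dtype=float)
    n, k = W_prev.shape
    B = pair_incidence(pairs, k)
    G = A.T @ A + lam * (B @ B.T)
    G = 0.5 * (G + G.T)
    G[np.diag_indices(k)] += tau_w
    F = X @ A + tau_w * W_prev  # one right-hand side per feature row
    W = np.empty((n, k))
    for i in range(n):
        W[i] = fnnls_solve(NormalEquations(G, F[i]))
    return W


def refresh_residual(X: np.ndarray, W: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Recompute ``R = X - W A^T`` from scratch (drift control)."""
    return X - W @ A.T
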