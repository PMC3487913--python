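"""Active-set non-negative least squares on normal equations (FNNLS).

Solves ``min_{x >= 0} 0.5 * x^T G x - f^T x`` given the Gram matrix ``G``
and linear term ``f`` directly — the Bro & de Jong reformulation of the
Lawson-Hanson active-set algorithm. Working from (G, f) avoids forming or
factorizing the stacked design matrix, which is what makes the Tikhonov and
related-base-vector component updates cheap: the same Gram matrix is shared
across many right-hand sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

__all__ = ["NormalEquations", "fnnls_solve"]


@dataclass
class NormalEquations:
    """Quadratic-program data: symmetric PSD Gram matrix G and linear term f."""

    G: np.ndarray
    f: np.ndarray

    def __post_init__(self):
        G = np.asarray(self.G, dtype=float)
        f = np.asarray(self.f, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("G must be a square matrix")
        if f.ndim != 1 or f.size != G.shape[0]:
            raise ValueError("f must be a vector matching G")
        scale = np.abs(G).max()
        if scale > 0 and np.abs(G - G.T).max() > 1e-10 * scale:
            raise ValueError("G must be symmetric")
        self.G = G
        self.f = f

    @property
    def d(self) -> int:
        return self.f.size


def _solve_restricted(G: np.ndarray, f: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = G[np.ix_(idx, idx)]
    try:
        return cho_solve(cho_factor(sub, lower=True), f[idx])
    except LinAlgError as exc:
        raise RuntimeError(
            "restricted Gram system is not positive definite; the caller "
            "likely omitted the proximal term that guarantees strict convexity"
        ) from exc


def fnnls_solve(
    ne: NormalEquations,
    tol: float | None = None,
    max_iter: int | None = None,
) -> np.ndarray:
    """Solve ``min_{x >= 0} 0.5 x^T G x - f^T x`` by the active-set strategy.

    Parameters
    ----------
    ne
        Normal-equation data with ``G`` positive definite (the solver's
        proximal terms guarantee this wherever it is called).
    tol
        KKT entry tolerance; default is the scale-aware
        ``1e-10 * (1 + max|f|)``.
    max_iter
        Inner-iteration budget, default ``30 * d``; exceeding it signals
        numerical trouble and raises.

    Returns
    -------
    x : ndarray
        The unique minimizer; satisfies the KKT certificate ``x >= 0``,
        ``(G x - f) >= -tol`` and ``x_i (G x - f)_i ~ 0``.
    """
    G, f, d = ne.G, ne.f, ne.d
    if tol is None:
        tol = 1e-10 * (1.0 + float(np.abs(f).max()))
    if max_iter is None:
        max_iter = 30 * d

    x = np.zeros(d)
    passive = np.zeros(d, dtype=bool)
    w = f.copy()  # negative KKT residual f - G x
    iters = 0

    while True:
        # pick the active coordinate with the most negative KKT residual
        candidates = np.where(~passive & (w > tol))[0]
        if candidates.size == 0:
            return x
        passive[candidates[np.argmax(w[candidates])]] = True

        while True:
            iters += 1
            if iters > max_iter:
                raise RuntimeError(f"FNNLS exceeded {max_iter} inner iterations")
            idx = np.flatnonzero(passive)
            z = _solve_restricted(G, f, idx)
            if np.all(z > 0):
                x = np.zeros(d)
                x[idx] = z
                break
            # step toward z until the first passive coordinate hits zero
            xi = x[idx]
            neg = z <= 0
            ratios = xi[neg] / (xi[neg] - z[neg])
            t = ratios.min()
            xi = xi + t * (z - xi)
            # Lawson-Hanson anti-cycling: drop the min-ratio coordinate
            # (ties resolved to the lowest index by argmin); clip any other
            # coordinate that reached the boundary as well
            drop_local = np.flatnonzero(neg)[np.argmin(ratios)]
            xi[drop_local] = 0.0
            xi[xi <= 0] = 0.0
            x = np.zeros(d)
            x[idx] = xi
            passive[idx[xi == 0]] = False
        w = f - G @ x
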