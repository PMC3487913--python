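"""Euclidean projection onto the alpha-simplex and first-order optimality.

The alpha-simplex Delta_alpha is the set of non-negative vectors whose
coordinates sum to alpha — the intersection of the non-negative orthant with
a hyperplane. Every mixing-column subproblem of the solver reduces to a
diagonal quadratic over Delta_alpha, whose exact minimizer is the Euclidean
projection of a constant vector. The projection is computed by sorting the
input descending and scanning once for the optimal support size.

A convex differentiable function attains its minimum over Delta_alpha at h
iff every partial derivative at a non-zero coordinate of h equals the
smallest partial derivative; :func:`simplex_optimality_gap` measures the
violation of that criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimplexPoint", "project_simplex", "simplex_optimality_gap"]


@dataclass(frozen=True)
class SimplexPoint:
    """A validated point of the alpha-simplex."""

    coords: np.ndarray
    alpha: float = 1.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 1 or coords.size < 1:
            raise ValueError("coords must be a non-empty 1-D vector")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if np.any(coords < 0):
            raise ValueError("simplex coordinates must be non-negative")
        if abs(coords.sum() - self.alpha) > 1e-12 * self.alpha * coords.size:
            raise ValueError(
                f"coordinates sum to {coords.sum()!r}, expected {self.alpha!r}"
            )


def _support_size_max_rule(c_sorted: np.ndarray, alpha: float) -> int:
    """q* = max{q : c_(q) - mu_q > 0} with mu_q = (sum of q largest - alpha)/q."""
    d = c_sorted.size
    q = np.arange(1, d + 1)
    mu = (np.cumsum(c_sorted) - alpha) / q
    positive = c_sorted - mu > 0
    # q=1 always qualifies: c_(1) - (c_(1) - alpha) = alpha > 0
    return int(q[positive][-1])


def _support_size_early_exit(c_sorted: np.ndarray, alpha: float) -> int:
    """Linear search: stop at the first q with q = d or mu_q >= c_(q+1).

    Equivalent to the max-q rule (the agreement is asserted by tests); kept
    as the reference restatement of the sorted scan.
    """
    d = c_sorted.size
    running = 0.0
    for q in range(1, d + 1):
        running += c_sorted[q - 1]
        mu = (running - alpha) / q
        if q == d or mu >= c_sorted[q]:
            return q
    raise AssertionError("unreachable: q = d always terminates the scan")


def project_simplex(c: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Euclidean projection of ``c`` onto the alpha-simplex.

    Returns the unique minimizer of ``0.5 * ||h - c||^2`` subject to
    ``h >= 0`` and ``sum(h) = alpha``. Entries of ``c`` may be negative.

    The support of the solution consists of the q* largest coordinates of
    ``c``, where q* is found in a single pass over the descending-sorted
    coordinates; the solution is ``h_i = max(c_i - mu, 0)`` with the
    multiplier ``mu = (sum of the q* largest coordinates - alpha) / q*``.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 1 or c.size < 1:
        raise ValueError("c must be a non-empty 1-D vector")
    if not np.all(np.isfinite(c)):
        raise ValueError("c contains non-finite entries")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    # stable sort on index so that ties are resolved deterministically
    order = np.argsort(-c, kind="stable")
    c_sorted = c[order]
    q_star = _support_size_max_rule(c_sorted, alpha)
    mu = (c_sorted[:q_star].sum() - alpha) / q_star
    return np.maximum(c - mu, 0.0)


def simplex_optimality_gap(grad: np.ndarray, h: np.ndarray) -> float:
    """Violation of the simplex first-order optimality criterion at ``h``.

    For the gradient ``grad`` of a convex block objective at a feasible
    point ``h``, returns ``max over {i : h_i > 0} of (grad_i - min_j
    grad_j)``. The value is zero exactly when every non-zero coordinate of
    ``h`` attains the smallest partial derivative — the necessary and
    sufficient minimum condition on the simplex.
    """
    grad = np.asarray(grad, dtype=float)
    h = np.asarray(h, dtype=float)
    if grad.shape != h.shape or grad.ndim != 1:
        raise ValueError("grad and h must be 1-D vectors of equal length")
    support = h > 0
    if not support.any():
        raise ValueError("h has no positive coordinate (not a simplex point)")
    return float(grad[support].max() - grad.min())
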