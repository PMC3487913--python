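"""Core data containers and the regularized factorization objective.

The model decomposes a non-negative expression matrix ``X`` (genes x samples)
as ``X ~ W @ A.T`` where ``W`` (genes x components) carries the base vectors
and ``A`` (samples x components) the mixing coefficients. Each column of ``A``
is constrained to the alpha-simplex (non-negative, summing exactly to
``alpha``), which locks the scale of the unregularized factor so that
scale-dependent penalties on ``W`` are well posed.

The objective minimized by the solver is

    F(W, A) = ||X - W A^T||_F^2 + lam * J(W)

with ``J`` one of: the entrywise l1 norm of ``W`` (sparsity), a Tikhonov term
``||L W||_F^2`` with a filter matrix ``L`` (smoothing), or the sum of squared
distances between designated pairs of base vectors (related components).
Proximal-point terms used inside block subproblems are *not* part of F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "FactorModel",
    "RegularizerSpec",
    "SolverConfig",
    "FitTrace",
    "objective_value",
    "objective_from_arrays",
    "regularizer_value",
    "regularizer_gradient",
    "pair_incidence",
    "sparsity_fraction",
]

REG_KINDS = ("none", "l1", "tikhonov", "related")

# Column sums of A may drift from alpha only by accumulated rounding.
SCALE_RTOL = 1e-9


def _as_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class ExpressionMatrix:
    """Non-negative genes x samples matrix with row/column labels."""

    values: np.ndarray
    row_ids: Sequence[str] = None
    col_ids: Sequence[str] = None

    def __post_init__(self):
        self.values = _as_matrix(self.values, "values")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("expression matrix must be at least 1x1")
        if np.any(self.values < 0):
            i, j = np.unravel_index(np.argmin(self.values), self.values.shape)
            raise ValueError(
                f"expression data must be non-negative (additive model); "
                f"found {self.values[i, j]:g} at row {i}, column {j}"
            )
        if self.row_ids is None:
            self.row_ids = [f"gene_{i + 1}" for i in range(n)]
        if self.col_ids is None:
            self.col_ids = [f"sample_{j + 1}" for j in range(m)]
        self.row_ids = list(map(str, self.row_ids))
        self.col_ids = list(map(str, self.col_ids))
        if len(self.row_ids) != n:
            raise ValueError(f"{len(self.row_ids)} row labels for {n} rows")
        if len(self.col_ids) != m:
            raise ValueError(f"{len(self.col_ids)} column labels for {m} columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FactorModel:
    """A factorization ``X ~ W @ A.T`` with exact scale control on ``A``.

    ``W`` is n x k (base vectors over features), ``A`` is m x k (per-sample
    mixing coefficients); every column of ``A`` sums to ``alpha``.
    """

    W: np.ndarray
    A: np.ndarray
    alpha: float = 1.0

    def __post_init__(self):
        self.W = _as_matrix(self.W, "W")
        self.A = _as_matrix(self.A, "A")
        self.alpha = float(self.alpha)
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.W.shape[1] != self.A.shape[1]:
            raise ValueError(
                f"W has {self.W.shape[1]} components but A has {self.A.shape[1]}"
            )
        if np.any(self.W < 0):
            raise ValueError("W must be non-negative")
        if np.any(self.A < 0):
            raise ValueError("A must be non-negative")
        colsums = self.A.sum(axis=0)
        if np.any(np.abs(colsums - self.alpha) > SCALE_RTOL * self.alpha):
            worst = int(np.argmax(np.abs(colsums - self.alpha)))
            raise ValueError(
                f"column {worst} of A sums to {colsums[worst]!r}, "
                f"expected alpha={self.alpha!r}"
            )

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def reconstruction(self) -> np.ndarray:
        """The model's fitted matrix ``W @ A.T`` (n x m)."""
        return self.W @ self.A.T

    def copy(self) -> "FactorModel":
        return FactorModel(self.W.copy(), self.A.copy(), self.alpha)


@dataclass(frozen=True)
class RegularizerSpec:
    """Which penalty J(W) to apply and its parameters.

    kind
        one of ``none | l1 | tikhonov | related``.
    weight
        the regularization weight ``lam`` (>= 0); ignored (treated as 0)
        for kind ``none``.
    filter
        n x n filter matrix ``L`` (tikhonov only).
    pairs
        iterable of 0-based component index pairs (i, j), i != j
        (related only).
    """

    kind: str = "none"
    weight: float = 0.0
    filter: np.ndarray | None = None
    pairs: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if self.kind not in REG_KINDS:
            raise ValueError(f"unknown regularizer kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("regularization weight must be non-negative")
        if self.kind == "tikhonov":
            if self.filter is None:
                raise ValueError("tikhonov regularization requires a filter matrix")
            L = _as_matrix(self.filter, "filter")
            if L.shape[0] != L.shape[1]:
                raise ValueError("filter matrix must be square (n x n)")
            object.__setattr__(self, "filter", L)
        if self.kind == "related":
            if not self.pairs:
                raise ValueError("related regularization requires a non-empty pair list")
            pairs = tuple((int(i), int(j)) for i, j in self.pairs)
            for i, j in pairs:
                if i == j or i < 0 or j < 0:
                    raise ValueError(f"invalid component pair ({i}, {j})")
            object.__setattr__(self, "pairs", pairs)

    @property
    def lam(self) -> float:
        """Effective weight (0 for kind='none')."""
        return 0.0 if self.kind == "none" else float(self.weight)


@dataclass
class SolverConfig:
    """Solver parameters.

    tau_a / tau_w are the proximal weights for the mixing/component blocks.
    ``None`` means the scale-aware default ``1e-6 * mean(X**2)`` is used at
    fit time; tau_a must resolve to a strictly positive value (the mixing
    subproblem degenerates when a base vector collapses to zero), whereas
    tau_w may be 0 when the component subproblem is strictly convex by
    itself (e.g. l1 with a non-zero mixing column).
    """

    k: int = 2
    alpha: float = 1.0
    tau_a: float | None = None
    tau_w: float | None = None
    tol: float = 1e-5
    max_iter: int = 500
    seed: int = 0
    init: str = "random"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tau_a is not None and self.tau_a <= 0:
            raise ValueError("tau_a must be strictly positive")
        if self.tau_w is not None and self.tau_w < 0:
            raise ValueError("tau_w must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        if self.init not in ("random", "custom"):
            raise ValueError("init must be 'random' or 'custom'")


@dataclass
class FitTrace:
    """Per-sweep diagnostics recorded by the solver.

    ``objective_converged`` is the pure relative-objective-decrease stopping
    criterion; ``converged`` additionally requires the KKT residuals to have
    dropped below 1e-3 of their initial values.
    """

    objective: np.ndarray = field(default_factory=lambda: np.empty(0))
    kkt_w: np.ndarray = field(default_factory=lambda: np.empty(0))
    kkt_a: np.ndarray = field(default_factory=lambda: np.empty(0))
    sparsity_w: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    objective_converged: bool = False
    sweeps: int = 0


def pair_incidence(pairs: Sequence[tuple[int, int]], k: int) -> np.ndarray:
    """Signed incidence matrix B (k x |pairs|): +1 at i, -1 at j per pair.

    ``||W @ B||_F^2`` then equals the sum of squared distances between the
    paired columns of W.
    """
    B = np.zeros((k, len(pairs)))
    for col, (i, j) in enumerate(pairs):
        if not (0 <= i < k) or not (0 <= j < k):
            raise ValueError(f"pair ({i}, {j}) out of range for k={k}")
        B[i, col] = 1.0
        B[j, col] = -1.0
    return B


def regularizer_value(W: np.ndarray, reg: RegularizerSpec) -> float:
    """J(W) for the given regularizer (without the weight lam)."""
    if reg.kind == "none":
        return 0.0
    if reg.kind == "l1":
        # entries are non-negative, so the plain sum is the entrywise l1 norm
        return float(W.sum())
    if reg.kind == "tikhonov":
        return float(np.linalg.norm(reg.filter @ W) ** 2)
    B = pair_incidence(reg.pairs, W.shape[1])
    return float(np.linalg.norm(W @ B) ** 2)


def regularizer_gradient(W: np.ndarray, reg: RegularizerSpec) -> np.ndarray:
    """Gradient (or, for l1, the constant one-sided derivative) of lam*J at W."""
    if reg.kind == "none" or reg.lam == 0:
        return np.zeros_like(W)
    if reg.kind == "l1":
        return np.full_like(W, reg.lam)
    if reg.kind == "tikhonov":
        L = reg.filter
        return 2.0 * reg.lam * (L.T @ (L @ W))
    B = pair_incidence(reg.pairs, W.shape[1])
    return 2.0 * reg.lam * (W @ (B @ B.T))


def objective_from_arrays(
    X: np.ndarray, W: np.ndarray, A: np.ndarray, reg: RegularizerSpec
) -> float:
    """F(W, A) on raw arrays (no invariant checks; used inside the solver)."""
    fit = float(np.linalg.norm(X - W @ A.T) ** 2)
    return fit + reg.lam * regularizer_value(W, reg)


def objective_value(
    X: "ExpressionMatrix | np.ndarray", model: FactorModel, reg: RegularizerSpec
) -> float:
    """Full objective ||X - W A^T||_F^2 + lam * J(W).

    Proximal-point terms belong to the block subproblems only and are never
    included here.
    """
    Xa = X.values if isinstance(X, ExpressionMatrix) else _as_matrix(X, "X")
    n, m = Xa.shape
    if model.W.shape[0] != n or model.A.shape[0] != m:
        raise ValueError(
            f"model shapes W{model.W.shape}, A{model.A.shape} do not match "
            f"data {Xa.shape}"
        )
    if reg.kind == "tikhonov" and reg.filter.shape[0] != n:
        raise ValueError("filter matrix must be n x n")
    return objective_from_arrays(Xa, model.W, model.A, reg)


def sparsity_fraction(W: np.ndarray, eps: float = 0.0) -> float:
    """Fraction of entries of W that are <= eps.

    The truncation-based l1 update produces exact zeros, so the default
    eps=0 counts exact zeros.
    """
    W = np.asarray(W)
    if W.size == 0:
        raise ValueError("sparsity of an empty matrix is undefined")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    return float(np.count_nonzero(W <= eps) / W.size)
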