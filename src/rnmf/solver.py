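"""The full regularized NMF procedure: block-coordinate descent with
proximal safeguards, KKT diagnostics, and sparsity-targeted weight search.

One sweep visits every block once. For the l1 and Tikhonov penalties the
component matrix is updated column by column with a cumulative rank-one
residual; for the related-base-vector penalty the component matrix is one
whole block (rows decouple) updated before the k mixing columns. Every
block update is an exact minimization, so the objective is non-increasing
sweep to sweep, and every column of the mixing matrix sums to alpha exactly
after every sweep.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np

from .model import (
    ExpressionMatrix,
    FactorModel,
    FitTrace,
    RegularizerSpec,
    SolverConfig,
    objective_from_arrays,
    regularizer_gradient,
    sparsity_fraction,
)
from .simplex import simplex_optimality_gap
from .updates import (
    refresh_residual,
    update_component_l1,
    update_component_related,
    update_component_tikhonov,
    update_mixing_column,
)

__all__ = [
    "init_factors",
    "fit",
    "kkt_residual_W",
    "kkt_residual_A",
    "lambda_for_sparsity",
    "order_components",
]

# residual refreshed from scratch every this many sweeps (drift control)
_REFRESH_EVERY = 10
# KKT residuals must drop below this times their initial value for the
# strict convergence flag (the objective criterion is tracked separately)
_KKT_DROP = 1e-3


def _data_array(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim != 2 or Xa.size == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(Xa)):
        raise ValueError("X contains non-finite entries")
    if np.any(Xa < 0):
        raise ValueError("X must be non-negative")
    return Xa


def init_factors(X, config: SolverConfig) -> FactorModel:
    """Random non-negative starting factors, deterministic given the seed.

    W entries are Uniform(0,1) scaled by mean(X)/k; A columns are
    Uniform(0,1) rescaled to sum exactly to alpha.
    """
    Xa = _data_array(X)
    n, m = Xa.shape
    k = config.k
    if k > min(n, m):
        warnings.warn(
            f"k={k} exceeds min(n, m)={min(n, m)}: overcomplete model",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    scale = float(Xa.mean()) / k
    if scale <= 0:
        scale = 1.0 / k
    W = rng.uniform(size=(n, k)) * scale
    A = rng.uniform(size=(m, k))
    A = A / A.sum(axis=0) * config.alpha
    return FactorModel(W, A, config.alpha)


def kkt_residual_W(X, model: FactorModel, reg: RegularizerSpec) -> float:
    """Max-norm of ``min(W, grad_W F)`` elementwise.

    ``grad_W F = -2 (X - W A^T) A + lam * dJ/dW`` (for l1 the subgradient
    constant lam enters both the W > 0 stationarity and the W = 0 boundary
    condition). The elementwise minimum with W vanishes exactly at a
    critical point: where W > 0 the gradient must be 0, where W = 0 it must
    be >= 0.
    """
    Xa = _data_array(X)
    W, A = model.W, model.A
    G = -2.0 * (Xa - W @ A.T) @ A + regularizer_gradient(W, reg)
    return float(np.abs(np.minimum(W, G)).max())


def kkt_residual_A(X, model: FactorModel) -> float:
    """Worst simplex optimality gap over the mixing columns.

    The gradient of the fit term with respect to A is
    ``2 (A (W^T W) - X^T W)``; for each column the gap is the largest
    excess of a partial derivative at a non-zero coordinate over the
    smallest partial derivative. Zero at a critical point.
    """
    Xa = _data_array(X)
    W, A = model.W, model.A
    D = 2.0 * (A @ (W.T @ W) - Xa.T @ W)
    gaps = [
        simplex_optimality_gap(D[:, l], A[:, l]) for l in range(A.shape[1])
    ]
    return float(max(gaps))


def _resolve_taus(Xa: np.ndarray, config: SolverConfig) -> tuple[float, float]:
    default = 1e-6 * float(np.mean(Xa**2))
    if default <= 0:
        default = 1e-6
    tau_a = config.tau_a if config.tau_a is not None else default
    tau_w = config.tau_w if config.tau_w is not None else default
    return float(tau_a), float(tau_w)


def fit(
    X,
    reg: RegularizerSpec | None = None,
    config: SolverConfig | None = None,
    init: FactorModel | None = None,
    callback: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
) -> tuple[FactorModel, FitTrace]:
    """Run the block-coordinate descent to convergence.

    Parameters
    ----------
    X
        Non-negative data matrix (ExpressionMatrix or array), n x m.
    reg
        Regularizer; default none (plain NMF with exact scale control).
    config
        Solver configuration; ``config.k`` and ``config.alpha`` are ignored
        in favor of the shapes of ``init`` when an initialization is given.
    init
        Optional starting factors (copied, never mutated).
    callback
        Optional ``callback(sweep, W, A)`` invoked after every sweep with
        the current factors (for logging/inspection).

    Returns
    -------
    (model, trace)
        The factorization and per-sweep diagnostics. Stops when the
        relative objective decrease falls below ``config.tol`` or the sweep
        budget is exhausted; the trace's ``converged`` flag additionally
        requires the KKT residuals to have dropped by 1e-3 from their
        initial values.
    """
    reg = reg if reg is not None else RegularizerSpec("none")
    config = config if config is not None else SolverConfig()
    Xa = _data_array(X)
    n, m = Xa.shape

    if init is not None:
        W = np.array(init.W, dtype=float)
        A = np.array(init.A, dtype=float)
        alpha = init.alpha
    else:
        start = init_factors(Xa, config)
        W, A, alpha = start.W, start.A, start.alpha
    k = W.shape[1]
    lam = reg.lam
    tau_a, tau_w = _resolve_taus(Xa, config)

    if reg.kind == "tikhonov" and reg.filter.shape[0] != n:
        raise ValueError("filter matrix must be n x n")

    R = refresh_residual(Xa, W, A)
    F_prev = objective_from_arrays(Xa, W, A, reg)
    model0 = FactorModel(W.copy(), A.copy(), alpha)
    kkt_w0 = kkt_residual_W(Xa, model0, reg)
    kkt_a0 = kkt_residual_A(Xa, model0)

    obj_hist, kktw_hist, kkta_hist, sp_hist = [], [], [], []
    objective_converged = converged = False
    sweeps = 0

    for sweep in range(1, config.max_iter + 1):
        sweeps = sweep
        if reg.kind == "related":
            W = update_component_related(Xa, A, W, lam, reg.pairs, tau_w)
            R = refresh_residual(Xa, W, A)
            for l in range(k):
                R += np.outer(W[:, l], A[:, l])
                A[:, l] = update_mixing_column(R, W[:, l], A[:, l], alpha, tau_a)
                R -= np.outer(W[:, l], A[:, l])
        else:
            for l in range(k):
                R += np.outer(W[:, l], A[:, l])
                if reg.kind == "tikhonov":
                    W[:, l] = update_component_tikhonov(
                        R, A[:, l], W[:, l], lam, reg.filter, tau_w
                    )
                else:  # none or l1 (none is l1 with lam = 0)
                    W[:, l] = update_component_l1(R, A[:, l], W[:, l], lam, tau_w)
                A[:, l] = update_mixing_column(R, W[:, l], A[:, l], alpha, tau_a)
                R -= np.outer(W[:, l], A[:, l])
        if sweep % _REFRESH_EVERY == 0:
            R = refresh_residual(Xa, W, A)
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(A))):
            raise FloatingPointError("non-finite values encountered during fit")

        F = objective_from_arrays(Xa, W, A, reg)
        cur = FactorModel(W.copy(), A.copy(), alpha)
        kkt_w = kkt_residual_W(Xa, cur, reg)
        kkt_a = kkt_residual_A(Xa, cur)
        obj_hist.append(F)
        kktw_hist.append(kkt_w)
        kkta_hist.append(kkt_a)
        sp_hist.append(sparsity_fraction(W))
        if callback is not None:
            callback(sweep, W, A)

        rel = (F_prev - F) / F_prev if F_prev > 0 else 0.0
        F_prev = F
        if rel < config.tol:
            objective_converged = True
            # absolute floor: residuals already at rounding noise count as
            # closed even when the starting point was (near-)critical
            floor = 1e-12 * (1.0 + float(np.abs(Xa).max()) ** 2)
            converged = kkt_w <= max(_KKT_DROP * kkt_w0, floor) and kkt_a <= max(
                _KKT_DROP * kkt_a0, floor
            )
            break

    trace = FitTrace(
        objective=np.array(obj_hist),
        kkt_w=np.array(kktw_hist),
        kkt_a=np.array(kkta_hist),
        sparsity_w=np.array(sp_hist),
        converged=converged,
        objective_converged=objective_converged,
        sweeps=sweeps,
    )
    return FactorModel(W, A, alpha), trace


def order_components(model: FactorModel) -> np.ndarray:
    """Component indices sorted by descending strength (||w_l||, ties by index)."""
    norms = np.linalg.norm(model.W, axis=0)
    return np.argsort(-norms, kind="stable")


def lambda_for_sparsity(
    X,
    target: float,
    config: SolverConfig,
    reg_kind: str = "l1",
    sparsity_tol: float = 0.02,
    max_doublings: int = 60,
    max_bisections: int = 25,
) -> tuple[float, FactorModel, FitTrace]:
    """Find the l1 weight whose converged fit has the requested zero fraction.

    Every evaluation refits from the *same* seeded initialization, so the
    achieved sparsity is a deterministic, (near-)monotone function of lam.
    A doubling search brackets the target from below, then at most
    ``max_bisections`` bisection steps home in; the best lam seen (closest
    achieved sparsity) and its fit are returned.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target sparsity must be in (0, 1)")
    if reg_kind != "l1":
        raise ValueError("sparsity targeting is defined for the l1 regularizer")
    Xa = _data_array(X)
    init0 = init_factors(Xa, config)

    best = None  # (gap, lam, model, trace, sparsity)

    def evaluate(lam: float):
        nonlocal best
        model, trace = fit(Xa, RegularizerSpec("l1", lam), config, init=init0)
        s = sparsity_fraction(model.W)
        gap = abs(s - target)
        if best is None or gap < best[0]:
            best = (gap, lam, model, trace, s)
        return s

    # bracket: double lam until the zero fraction reaches the target
    scale = float(Xa.mean())
    lam = 1e-6 * (scale if scale > 0 else 1.0)
    lo, hi = 0.0, None
    for _ in range(max_doublings):
        s = evaluate(lam)
        if s >= target:
            hi = lam
            break
        lo = lam
        lam *= 2.0
    if hi is None:
        raise RuntimeError(
            f"target sparsity {target} not reached within the bracket budget"
        )

    for _ in range(max_bisections):
        if best[0] <= 0.25 * sparsity_tol:
            break
        mid = 0.5 * (lo + hi)
        s = evaluate(mid)
        if s >= target:
            hi = mid
        else:
            lo = mid

    _, lam_best, model, trace, _ = best
    return lam_best, model, trace
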