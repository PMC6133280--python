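"""Fitting with missing values by majorization-minimization.

With missing cells M, the loss is summed over observed cells only:

    f(U) = 1/2 sum_{(i,j) observed} (X_ij - U_ij)^2 + gamma * sum_i w_i ||U_.i - U_.i+1||

Still convex, so the global solution is attainable.  The surrogate
``g(U | U^k)`` adds ``1/2 sum_{(i,j) missing} (U_ij - U^k_ij)^2``; it
majorizes f and touches it at U^k, so alternating (a) completing the
working matrix T with current centroid values on the missing cells and
(b) re-solving the complete-data problem on T yields a non-increasing
sequence f(U^k) converging to the global optimum.  The missing entries
of the final U double as model-based imputations (region-mean fill-in);
no separate imputation step is ever run.

Masks are cell-level: any pattern of missing cells is accepted, which
the cross-validation scheme relies on to punch element-wise holes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import RunConfig, ValidationError
from .solver import FusionFit, fit_spacc
from .weights import WeightChain

logger = logging.getLogger("spacc")


@dataclass
class MissingFit:
    """Missing-data solution: inner fit, completed matrix, MM trace.

    ``imputed`` carries observed entries of X verbatim and fitted centroid
    values on missing cells; ``surrogate_trace`` records the true
    objective f(U^k) at every outer iteration (non-increasing).
    """

    fit: FusionFit
    imputed: np.ndarray
    outer_iters: int
    surrogate_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def objective(self) -> float:
        return float(self.surrogate_trace[-1])


def objective_missing(X: np.ndarray, U: np.ndarray, mask: np.ndarray,
                      chain: WeightChain, gamma: float) -> float:
    """Observed-cell loss plus fusion penalty (the true objective f)."""
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValidationError("all cells are missing")
    if not np.isfinite(U).all():
        raise ValidationError("U contains non-finite entries")
    resid = np.where(mask, 0.0, X - U)
    loss = 0.5 * float((resid ** 2).sum())
    diffs = U[:, :-1] - U[:, 1:]
    norms = np.sqrt((diffs ** 2).sum(axis=0))
    return loss + gamma * float((chain.weights * norms).sum())


def surrogate_objective(X, U, U_k, mask, chain, gamma) -> float:
    """The MM surrogate g(U | U_k): adds a proximity term on missing cells."""
    extra = 0.5 * float((np.where(mask, U - U_k, 0.0) ** 2).sum())
    return objective_missing(X, U, mask, chain, gamma) + extra


def initial_fill(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-subject mean of observed entries (overall mean as fallback)."""
    obs = np.where(mask, np.nan, X)
    with np.errstate(invalid="ignore"):
        row_means = np.nanmean(obs, axis=1, keepdims=True)
    overall = np.nanmean(obs)
    row_means = np.where(np.isfinite(row_means), row_means, overall)
    return np.where(mask, np.broadcast_to(row_means, X.shape), X)


def fit_spacc_missing(X: np.ndarray, mask: np.ndarray, chain: WeightChain,
                      gamma: float, config: RunConfig | None = None,
                      warm: MissingFit | None = None,
                      tol: float | None = None, max_iter: int | None = None,
                      outer_tol: float | None = None) -> MissingFit:
    """MM loop: complete the matrix with current centroids, re-solve, repeat.

    With an empty mask this reduces to a single complete-data solve and
    returns it unchanged.  Every subproblem (chain segment) must contain
    at least one observed cell; fully missing probe columns *within* a
    segment are fine -- the fusion penalty propagates neighboring values
    into them.
    """
    config = config or RunConfig()
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != X.shape:
        raise ValidationError("mask shape must match X")
    tol = config.tol if tol is None else tol
    max_iter = config.max_iter if max_iter is None else max_iter
    outer_tol = config.outer_tol if outer_tol is None else outer_tol

    if not mask.any():
        fit = fit_spacc(X, chain, gamma, config,
                        warm=warm.fit if warm is not None else None,
                        tol=tol, max_iter=max_iter)
        return MissingFit(fit=fit, imputed=X.copy(), outer_iters=0,
                          surrogate_trace=np.array(
                              [objective_missing(X, fit.U, mask, chain, gamma)]))

    for (s, e) in chain.segments:
        if mask[:, s:e].all():
            raise ValidationError(
                f"subproblem over probes [{s},{e}) has no observed cells")

    if warm is not None:
        T = X.copy()
        T[mask] = warm.fit.U[mask]
        inner_warm = warm.fit
    else:
        T = initial_fill(X, mask)
        inner_warm = None

    trace = []
    f_prev = np.inf
    fit = None
    outer = 0
    for outer in range(1, config.outer_max_iter + 1):
        fit = fit_spacc(T, chain, gamma, config, warm=inner_warm,
                        tol=tol, max_iter=max_iter)
        inner_warm = fit
        f = objective_missing(X, fit.U, mask, chain, gamma)
        trace.append(f)
        T[mask] = fit.U[mask]
        if abs(f_prev - f) <= outer_tol * (1.0 + abs(f)):
            break
        f_prev = f
    return MissingFit(fit=fit, imputed=T, outer_iters=outer,
                      surrogate_trace=np.asarray(trace))
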