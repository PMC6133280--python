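"""AMA solver for the spatial convex clustering problem.

The fitted object solves, per chain of probes,

    minimize_U  1/2 ||X - U||_F^2  +  gamma * sum_i w_i ||U_{.,i} - U_{.,i+1}||_2

a convex problem whose solution path fuses adjacent probe centroids as
``gamma`` grows.  Introducing ``V_{.,i} = U_{.,i} - U_{.,i+1}`` and dual
variables ``Lambda``, the alternating minimization algorithm (AMA)
iterates a closed-form U-update, a blockwise group soft-threshold
V-update, and a dual ascent Lambda-update.  AMA is proximal gradient
ascent on the dual; the chain difference operator has squared spectral
norm below 4, so any step ``nu <= 0.25`` converges.  An optional Nesterov
acceleration of the dual sequence (on by default) leaves the fixed point
unchanged.

Fused gaps are read off the fitted difference matrix ``V``: after
element-wise thresholding, probes i and i+1 belong to one region iff the
whole thresholded column ``V_{.,i}`` is zero (and the gap carries
positive weight).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import ProbeMatrix, RegionPartition, RunConfig, ValidationError
from .weights import WeightChain

logger = logging.getLogger("spacc")

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:        # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(fn):
            return fn
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=False)
def _ama_kernel(Xt, w, gamma, nu, tol, max_iter, Lam, accelerate):
    """Hot loop of the AMA iteration in probe-major (p, n) layout.

    Returns (Ut, Vt, Lam, n_iter, converged) with Ut (p, n), Vt/Lam
    (p-1, n).  Implements the same three updates as the numpy path,
    including the gradient-based restart of the Nesterov sequence.
    """
    p, n = Xt.shape
    m = p - 1
    U = Xt.copy()
    U_prev = Xt.copy()
    V = np.zeros((m, n))
    Lam_old = Lam.copy()     # accepted iterate Lambda^k
    Lam_t = Lam.copy()       # extrapolated sequence
    Lam_new = Lam.copy()
    t_k = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # U-update (closed form given the duals)
        for j in range(n):
            U[0, j] = Xt[0, j] + Lam_t[0, j]
            U[m, j] = Xt[m, j] - Lam_t[m - 1, j]
        for i in range(1, m):
            for j in range(n):
                U[i, j] = Xt[i, j] + Lam_t[i, j] - Lam_t[i - 1, j]
        # V-update (group soft-threshold) + Lambda-update (dual ascent)
        restart_dot = 0.0
        feas_max = 0.0
        for i in range(m):
            sq = 0.0
            for j in range(n):
                g = U[i, j] - U[i + 1, j] - Lam_t[i, j] / nu
                V[i, j] = g
                sq += g * g
            norm = np.sqrt(sq)
            th = gamma * w[i] / nu
            shrink = 0.0
            if norm > th:
                shrink = 1.0 - th / norm
            feas_sq = 0.0
            for j in range(n):
                v = shrink * V[i, j]
                V[i, j] = v
                du = U[i, j] - U[i + 1, j]
                lam = Lam_t[i, j] + nu * (v - du)
                restart_dot += (Lam_t[i, j] - lam) * (lam - Lam_old[i, j])
                feas_sq += (v - du) * (v - du)
                Lam_new[i, j] = lam
            if feas_sq > feas_max:
                feas_max = feas_sq
        # Nesterov momentum with gradient-based adaptive restart
        if accelerate:
            if t_k > 1.0 and restart_dot > 0.0:
                t_k = 1.0
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
            beta = (t_k - 1.0) / t_next
            for i in range(m):
                for j in range(n):
                    new = Lam_new[i, j]
                    Lam_t[i, j] = new + beta * (new - Lam_old[i, j])
                    Lam_old[i, j] = new
            t_k = t_next
        else:
            for i in range(m):
                for j in range(n):
                    Lam_t[i, j] = Lam_new[i, j]
                    Lam_old[i, j] = Lam_new[i, j]
        # convergence: relative U change and primal feasibility
        if it > 1:
            num = 0.0
            den = 0.0
            for i in range(p):
                for j in range(n):
                    d = U[i, j] - U_prev[i, j]
                    num += d * d
                    den += U_prev[i, j] * U_prev[i, j]
            rel = np.sqrt(num) / (1.0 + np.sqrt(den))
            err = rel if rel > np.sqrt(feas_max) else np.sqrt(feas_max)
            if err <= tol:
                converged = True
                break
        for i in range(p):
            for j in range(n):
                U_prev[i, j] = U[i, j]
    return U, V, Lam_old, it, converged


@dataclass
class FusionFit:
    """Solution and solver state for one fitted problem.

    U is the (n, p) centroid matrix; V the (n, p-1) fitted adjacent
    differences; Lambda the dual variables; ``objective_trace`` holds the
    primal objective evaluated at U per recorded iteration (last entry =
    final value).
    """

    U: np.ndarray
    V: np.ndarray
    Lambda: np.ndarray
    gamma: float
    nu: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def group_soft_threshold(g: np.ndarray, t: float) -> np.ndarray:
    """Blockwise soft threshold: ``(1 - t/||g||_2)_+ * g`` (0 when ||g|| <= t)."""
    if t < 0:
        raise ValidationError("threshold must be >= 0")
    g = np.asarray(g, dtype=float)
    if t == 0:
        return g.copy()
    norm = np.linalg.norm(g)
    if norm <= t:
        return np.zeros_like(g)
    return (1.0 - t / norm) * g


def spacc_objective(X: np.ndarray, U: np.ndarray, chain: WeightChain,
                    gamma: float) -> float:
    """Primal objective: 1/2 squared Frobenius loss + weighted fusion penalty."""
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    if not np.isfinite(U).all():
        raise ValidationError("U contains non-finite entries")
    if np.isnan(X).any():
        raise ValidationError(
            "X contains NaN; use the missing-data objective instead")
    loss = 0.5 * float(((X - U) ** 2).sum())
    diffs = U[:, :-1] - U[:, 1:]
    norms = np.sqrt((diffs ** 2).sum(axis=0))
    return loss + gamma * float((chain.weights * norms).sum())


def _penalty_norms(U: np.ndarray) -> np.ndarray:
    d = U[:, :-1] - U[:, 1:]
    return np.sqrt((d ** 2).sum(axis=0))


def _full_fusion_solution(X, w, gamma):
    """Exact solution when gamma is at or past the full-fusion point.

    U is the per-subject mean; the duals are the cumulative sums
    ``Lambda_k = sum_{j<=k} (Xbar - X_j)``, which satisfy the stationarity
    condition exactly and are dual feasible iff gamma >= the full-fusion
    point.  Returns None when infeasible (gamma below the point).
    """
    mean = X.mean(axis=1, keepdims=True)
    Lam = np.cumsum(mean - X, axis=1)[:, :-1]
    norms = np.sqrt((Lam ** 2).sum(axis=0))
    if (norms > gamma * w).any():
        return None
    U = np.broadcast_to(mean, X.shape).copy()
    return U, np.zeros_like(Lam), Lam


def _ama_chain(X, w, gamma, nu, tol, max_iter, accelerate=True,
               warm=None, record_trace=False):
    """Run AMA on one chain.  Returns (U, V, Lambda, n_iter, converged, trace)."""
    n, p = X.shape
    if p == 1:
        U = X.copy()
        return U, np.empty((n, 0)), np.empty((n, 0)), 0, True, \
            [0.0] if record_trace else []
    if not record_trace and gamma > 0:
        exact = _full_fusion_solution(X, w, gamma)
        if exact is not None:
            U, V, Lam = exact
            return U, V, Lam, 0, True, []
    if _HAVE_NUMBA and not record_trace:
        Lam0 = (np.ascontiguousarray(warm[2].T) if warm is not None
                else np.zeros((p - 1, n)))
        Ut, Vt, Lamt, it, conv = _ama_kernel(
            np.ascontiguousarray(X.T), np.ascontiguousarray(w, dtype=float),
            float(gamma), float(nu), float(tol), int(max_iter), Lam0,
            bool(accelerate))
        return (np.ascontiguousarray(Ut.T), np.ascontiguousarray(Vt.T),
                np.ascontiguousarray(Lamt.T), it, conv, [])
    if warm is not None:
        Lam = warm[2].copy()
    else:
        Lam = np.zeros((n, p - 1))
    thresh = gamma * w / nu
    Lam_tilde = Lam
    t_k = 1.0
    trace = []
    U = V = None
    U_prev = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # U-update (closed form given the dual variables)
        U = X.copy()
        U[:, :-1] += Lam_tilde
        U[:, 1:] -= Lam_tilde
        DU = U[:, :-1] - U[:, 1:]
        # V-update: blockwise group soft-threshold
        G = DU - Lam_tilde / nu
        norms = np.sqrt((G ** 2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            shrink = 1.0 - thresh / norms
        shrink[norms == 0] = 0.0
        np.clip(shrink, 0.0, None, out=shrink)
        V = shrink * G
        # Lambda-update (dual ascent)
        Lam_new = Lam_tilde + nu * (V - DU)
        if accelerate:
            # gradient-based adaptive restart of the Nesterov sequence
            if t_k > 1.0 and float(((Lam_tilde - Lam_new) *
                                    (Lam_new - Lam)).sum()) > 0.0:
                t_k = 1.0
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
            Lam_tilde = Lam_new + ((t_k - 1.0) / t_next) * (Lam_new - Lam)
            t_k = t_next
        else:
            Lam_tilde = Lam_new
        Lam = Lam_new
        if record_trace:
            loss = 0.5 * float(((X - U) ** 2).sum())
            trace.append(loss + gamma * float((w * _penalty_norms(U)).sum()))
        # convergence: relative U change and primal feasibility
        if U_prev is not None:
            rel = np.linalg.norm(U - U_prev) / (1.0 + np.linalg.norm(U_prev))
            feas = np.sqrt(((V - DU) ** 2).sum(axis=0)).max() if p > 1 else 0.0
            if max(rel, feas) <= tol:
                converged = True
                break
        U_prev = U
    return U, V, Lam, it, converged, trace


def gamma_full_fusion(X: np.ndarray, chain: WeightChain) -> float:
    """Smallest gamma at which every positive-weight gap is fused.

    Within a segment the fully fused solution sets every column to the
    per-subject segment mean; dual feasibility holds iff
    ``gamma >= max_k ||sum_{j<=k} (X_j - Xbar)||_2 / w_k`` over interior
    gaps k, which is therefore the exact full-fusion point.
    """
    gmax = 0.0
    for (s, e) in chain.segments:
        if e - s < 2:
            continue
        Xs = X[:, s:e]
        centered = Xs - Xs.mean(axis=1, keepdims=True)
        cums = np.cumsum(centered, axis=1)[:, :-1]
        norms = np.sqrt((cums ** 2).sum(axis=0))
        w = chain.weights[s:e - 1]
        gmax = max(gmax, float((norms / w).max()))
    return gmax


def default_gamma_grid(X: np.ndarray, chain: WeightChain,
                       config: RunConfig) -> np.ndarray:
    """Log-spaced grid ending at the adaptive full-fusion point."""
    if config.gamma_grid is not None:
        return config.gamma_grid
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        fill = np.nanmean(X, axis=1, keepdims=True)
        fill = np.where(np.isfinite(fill), fill, np.nanmean(X))
        X = np.where(np.isnan(X), np.broadcast_to(fill, X.shape), X)
    gmax = gamma_full_fusion(X, chain)
    if gmax <= 0:
        gmax = 1.0
    return np.geomspace(config.gamma_min_ratio * gmax, gmax, config.n_gamma)


def fit_spacc(X: np.ndarray, chain: WeightChain, gamma: float,
              config: RunConfig | None = None, warm: FusionFit | None = None,
              record_trace: bool = False, split: bool = True,
              tol: float | None = None, max_iter: int | None = None) -> FusionFit:
    """Solve the fusion problem on a complete (no-NaN) matrix.

    Zero-weight gaps make the penalty separable, so by default each
    segment of the chain is solved independently and the pieces are
    concatenated; ``split=False`` runs one joint chain (identical
    solution, useful for verification).  ``warm`` seeds the dual
    variables from a previous fit at a nearby gamma.
    """
    config = config or RunConfig()
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("X must be finite; route NaNs through "
                              "fit_spacc_missing")
    if gamma < 0:
        raise ValidationError("gamma must be >= 0")
    n, p = X.shape
    if chain.p != p:
        raise ValidationError(f"chain covers {chain.p} probes, X has {p}")
    tol = config.tol if tol is None else tol
    max_iter = config.max_iter if max_iter is None else max_iter

    segments = chain.segments if split else [(0, p)]
    U = np.empty_like(X)
    V = np.zeros((n, p - 1))
    Lam = np.zeros((n, p - 1))
    n_iter, converged, traces = 0, True, []
    for (s, e) in segments:
        w = chain.weights[s:e - 1]
        warm_seg = None
        if warm is not None:
            warm_seg = (warm.U[:, s:e], warm.V[:, s:e - 1],
                        warm.Lambda[:, s:e - 1])
        Us, Vs, Ls, it, conv, trace = _ama_chain(
            X[:, s:e], w, gamma, config.nu, tol, max_iter,
            accelerate=config.accelerate, warm=warm_seg,
            record_trace=record_trace)
        U[:, s:e] = Us
        V[:, s:e - 1] = Vs
        Lam[:, s:e - 1] = Ls
        n_iter = max(n_iter, it)
        converged = converged and conv
        traces.append(trace)
    # across zero-weight gaps V is the plain difference (penalty absent there)
    for (s, e) in segments:
        if e < p:
            V[:, e - 1] = U[:, e - 1] - U[:, e]
    if not converged:
        warnings.warn(f"AMA did not converge within {max_iter} iterations "
                      f"(gamma={gamma:.4g})", RuntimeWarning, stacklevel=2)
    if record_trace:
        # sum per-segment traces, extending each with its final value
        L = max((len(t) for t in traces), default=0)
        total = np.zeros(L)
        for t in traces:
            if not t:
                continue
            t = np.asarray(t)
            total[:len(t)] += t
            total[len(t):] += t[-1]
        trace_arr = total
    else:
        trace_arr = np.array([spacc_objective(X, U, chain, gamma)])
    fit = FusionFit(U=U, V=V, Lambda=Lam, gamma=gamma, nu=config.nu,
                    n_iter=n_iter, converged=converged,
                    objective_trace=trace_arr)
    return fit


def extract_partition(fit: FusionFit, chain: WeightChain,
                      threshold_level: float, probes: ProbeMatrix | None = None
                      ) -> RegionPartition:
    """Threshold the fitted differences and merge fused runs into regions.

    Entries with ``|V_ij| < threshold_level`` are set to zero (strict
    inequality: entries exactly at the level survive).  Probes i and i+1
    merge iff the whole thresholded column is zero and the gap weight is
    positive; regions are the connected runs of merges.
    """
    if threshold_level < 0:
        raise ValidationError("threshold_level must be >= 0")
    V = np.where(np.abs(fit.V) < threshold_level, 0.0, fit.V)
    fused = (V == 0).all(axis=0) & (chain.weights > 0)
    chrom = probes.chrom if probes is not None else None
    return RegionPartition.from_fused_gaps(fused, chrom=chrom)
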