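"""Synthetic data generators with ground-truth region structure.

Three generative models, matching the study conditions under which the
method's recovery behavior is characterized:

* **CNV mean-shift**: ``X_ij = mu_j + s_{i,r(j)} m_{i,r(j)} + eps_ij``
  with per-(subject, region) shift indicators ``s ~ Bernoulli(q)``,
  signed magnitudes ``m ~ +/- Uniform(a, b)`` (sign equiprobable), and
  iid Gaussian noise.  Difficulty regimes: magnitude (a, b) = (0.2, 0.4)
  easy / (0.05, 0.3) hard at sigma = 0.1, and q = 0.7 easy / 0.5 hard.

* **Methylation Gaussian copula**: latent ``z_i ~ N_p(0, Sigma)`` with
  blockwise exponential spatial covariance -- ``exp(-d_ij/sigma_w)``
  within a true region, ``exp(-d_ij/sigma_b)`` between -- mapped through
  the standard normal CDF so beta-values ``X = Phi(z)`` lie in (0, 1)
  with uniform marginals.  Scenarios HIGH/MEDIUM/LOW fix sigma_w = 100 kb
  and sigma_b = 0.01 / 0.1 / 1 kb.

* **rEWAS response model**: per-subject region means ``m_ig ~ Beta(2,2)``,
  probe values ``X_ij ~ Beta(alpha, tau)`` with ``E[X_ij] = m_ig``
  (alpha = kappa*m, tau = kappa*(1-m)), and a linear response
  ``y_i = sum_l beta_l m_{i,g_l} + eps_i`` over d causal regions with
  ``beta_l ~ N(beta_seed, beta_seed)`` (second parameter a variance).
  The reference scale is n = 94 subjects against p = 23,515 probes.

Every generator draws one RNG substream per subject, so growing n never
changes earlier subjects; global draws (causal regions, coefficients)
use a dedicated substream.  True probe layouts are synthetic: the real
studies seed region boundaries from observed segmentations, and
:func:`make_layout` stands in with contiguous regions of configurable
length and spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .core_io import ProbeMatrix, RegionPartition, ValidationError, logger

# Named study conditions ----------------------------------------------------

CNV_EASY_MAG = {"a": 0.2, "b": 0.4, "sigma_noise": 0.1}
CNV_HARD_MAG = {"a": 0.05, "b": 0.3, "sigma_noise": 0.1}
CNV_Q_EASY = 0.7
CNV_Q_HARD = 0.5

# (sigma_w, sigma_b) in basepairs
METH_HIGH = (100_000.0, 10.0)
METH_MEDIUM = (100_000.0, 100.0)
METH_LOW = (100_000.0, 1_000.0)

EASY_SHAPE = (30, 120)   # long segments, easier to detect
HARD_SHAPE = (5, 30)     # short fragmented segments

REWAS_FULL_SCALE = {"n": 94, "p": 23_515}


@dataclass
class SimTruth:
    """Ground-truth partition plus generative parameters of one draw."""

    partition: RegionPartition
    seed: int
    cnv_params: dict = field(default_factory=dict)
    meth_params: dict = field(default_factory=dict)
    rewas_params: dict = field(default_factory=dict)


def make_layout(p: int, n_regions: int, region_size_range=(30, 120),
                within_gap_bp: int = 1000, between_gap_bp: int = 1000,
                seed: int = 0, chrom: str = "chr1"):
    """Synthetic probe layout: contiguous true regions tiling p probes.

    Draws ``n_regions`` sizes uniformly from ``region_size_range`` and
    keeps drawing until all p probes are covered (the final region is
    truncated to fit), so ``n_regions`` is a minimum.  Probes within a
    region are ``within_gap_bp`` apart; consecutive regions are separated
    by ``between_gap_bp``.

    Returns ``(positions, RegionPartition)`` with 1-based positions.
    """
    lo, hi = region_size_range
    if lo < 1 or hi < lo:
        raise ValidationError("region_size_range must satisfy 1 <= lo <= hi")
    if n_regions * lo > p:
        raise ValidationError(
            f"{n_regions} regions of >= {lo} probes exceed p={p}")
    rng = np.random.default_rng(seed)
    sizes = list(rng.integers(lo, hi + 1, size=n_regions))
    while sum(sizes) < p:
        sizes.append(int(rng.integers(lo, hi + 1)))
    # trim to exactly p probes: drop whole regions from the end, then shorten
    excess = sum(sizes) - p
    while excess >= sizes[-1]:
        excess -= sizes.pop()
    sizes[-1] -= excess
    assignment = np.repeat(np.arange(len(sizes)), sizes)
    steps = np.full(p, within_gap_bp, dtype=np.int64)
    steps[0] = 0
    boundary = np.flatnonzero(np.diff(assignment) != 0) + 1
    steps[boundary] = between_gap_bp
    positions = 1 + np.cumsum(steps)
    part = RegionPartition(assignment=assignment)
    part.attach_chrom(np.full(p, chrom, dtype=object))
    return positions, part


def _probe_matrix(X, positions, chrom, data_kind):
    p = X.shape[1]
    return ProbeMatrix.from_arrays(
        values=X, chrom=np.full(p, chrom, dtype=object), pos=positions,
        data_kind=data_kind, sort=False)


def simulate_cnv(positions, partition: RegionPartition, q: float,
                 a: float, b: float, sigma_noise: float, n: int, seed: int,
                 baseline=0.0, chrom: str = "chr1"):
    """Mean-shift CNV model over a true region layout.

    Per subject i and region g: shift indicator ``s ~ Bernoulli(q)``,
    magnitude ``m = sign * Uniform(a, b)`` with equiprobable sign; probe
    value ``X_ij = mu_j + s m + eps`` with ``eps ~ N(0, sigma_noise)``.
    ``baseline`` is the per-probe mu_j (scalar or length-p array).
    """
    if not 0 <= q <= 1:
        raise ValidationError("q must be in [0, 1]")
    if not 0 < a <= b:
        raise ValidationError("need 0 < a <= b")
    if sigma_noise <= 0:
        raise ValidationError("sigma_noise must be > 0")
    p = partition.p
    G = partition.n_regions
    assignment = partition.assignment
    mu = np.broadcast_to(np.asarray(baseline, dtype=float), (p,))
    streams = np.random.SeedSequence(seed).spawn(n)
    X = np.empty((n, p))
    s_mat = np.empty((n, G), dtype=np.int64)
    m_mat = np.empty((n, G))
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        s = rng.binomial(1, q, size=G)
        sign = rng.choice([-1.0, 1.0], size=G)
        mag = rng.uniform(a, b, size=G)
        eps = rng.normal(0.0, sigma_noise, size=p)
        m = sign * mag
        X[i] = mu + (s * m)[assignment] + eps
        s_mat[i] = s
        m_mat[i] = m
    probes = _probe_matrix(X, positions, chrom, "cnv")
    truth = SimTruth(partition=partition, seed=seed,
                     cnv_params={"q": q, "a": a, "b": b,
                                 "sigma_noise": sigma_noise, "baseline": mu,
                                 "s": s_mat, "m": m_mat})
    return probes, truth


def _blockwise_covariance(positions, assignment, sigma_w, sigma_b):
    pos = np.asarray(positions, dtype=float)
    d = np.abs(pos[:, None] - pos[None, :])
    same = assignment[:, None] == assignment[None, :]
    return np.where(same, np.exp(-d / sigma_w), np.exp(-d / sigma_b))


def simulate_methylation(positions, partition: RegionPartition,
                         sigma_w: float, sigma_b: float, n: int, seed: int,
                         chrom: str = "chr1"):
    """Gaussian-copula methylation model with blockwise spatial covariance.

    The blockwise construction is not guaranteed positive semidefinite;
    eigenvalues are clipped at 1e-8 and a warning is logged if the repair
    perturbs any covariance entry by more than 0.05.
    """
    if not sigma_w > sigma_b > 0:
        raise ValidationError("need sigma_w > sigma_b > 0")
    p = partition.p
    Sigma = _blockwise_covariance(positions, partition.assignment,
                                  sigma_w, sigma_b)
    eigval, eigvec = np.linalg.eigh(Sigma)
    clipped = np.clip(eigval, 1e-8, None)
    max_pert = 0.0
    if (eigval < 1e-8).any():
        repaired = (eigvec * clipped) @ eigvec.T
        max_pert = float(np.abs(repaired - Sigma).max())
        if max_pert > 0.05:
            logger.warning("PSD repair perturbed covariance by up to %.4g",
                           max_pert)
    A = eigvec * np.sqrt(clipped)   # z = A @ g has covariance ~ Sigma
    streams = np.random.SeedSequence(seed).spawn(n)
    X = np.empty((n, p))
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        z = A @ rng.standard_normal(p)
        X[i] = ndtr(z)
    eps = np.finfo(float).tiny
    np.clip(X, eps, 1.0 - 1e-16, out=X)
    probes = _probe_matrix(X, positions, chrom, "methylation")
    truth = SimTruth(partition=partition, seed=seed,
                     meth_params={"sigma_w": sigma_w, "sigma_b": sigma_b,
                                  "max_psd_perturbation": max_pert})
    return probes, truth


def simulate_rewas(positions, partition: RegionPartition, d: int,
                   beta_seed: float, sigma_noise: float, n: int, seed: int,
                   precision_kappa: float = 20.0, chrom: str = "chr1"):
    """Region-mean association model: beta-distributed probes, linear response.

    Returns ``(ProbeMatrix, y, SimTruth)``.  The d causal regions are
    sampled without replacement; coefficients ``beta_l ~ N(beta_seed,
    beta_seed)`` (variance beta_seed).  ``precision_kappa`` sets the
    within-region probe concentration: X_ij ~ Beta(kappa*m, kappa*(1-m)),
    giving E[X] = m and Var(X) = m(1-m)/(kappa+1).  Signal-to-noise is
    governed by beta_seed relative to sigma_noise**2.
    """
    G = partition.n_regions
    if d > G:
        raise ValidationError(f"d={d} causal regions but only G={G} regions")
    if d < 0:
        raise ValidationError("d must be >= 0")
    if beta_seed <= 0:
        raise ValidationError("beta_seed must be > 0")
    if precision_kappa <= 2:
        raise ValidationError("precision_kappa must be > 2")
    p = partition.p
    assignment = partition.assignment
    streams = np.random.SeedSequence(seed).spawn(n + 1)
    global_rng = np.random.default_rng(streams[n])
    causal = np.sort(global_rng.choice(G, size=d, replace=False))
    betas = global_rng.normal(beta_seed, np.sqrt(beta_seed), size=d)
    X = np.empty((n, p))
    M = np.empty((n, G))
    eps = np.empty(n)
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        m = rng.beta(2.0, 2.0, size=G)
        mj = m[assignment]
        X[i] = rng.beta(precision_kappa * mj, precision_kappa * (1.0 - mj))
        eps[i] = rng.normal(0.0, sigma_noise)
        M[i] = m
    y = M[:, causal] @ betas + eps
    tiny = np.finfo(float).tiny
    np.clip(X, tiny, 1.0 - 1e-16, out=X)
    probes = _probe_matrix(X, positions, chrom, "methylation")
    truth = SimTruth(partition=partition, seed=seed,
                     rewas_params={"causal_regions": causal, "betas": betas,
                                   "beta_seed": beta_seed,
                                   "sigma_noise": sigma_noise,
                                   "precision_kappa": precision_kappa,
                                   "region_means": M})
    return probes, y, truth
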