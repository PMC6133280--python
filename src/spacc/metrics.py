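"""Partition-recovery and discovery-recovery scores.

Pair-counting indices (Rand, adjusted Rand, Jaccard) are computed from
the 2x2 table over all probe pairs -- a: together in both partitions,
b / c: together in exactly one, d: together in neither.  The Variation
of Information is the information-theoretic distance
``VI = H(P) + H(Q) - 2 I(P, Q)`` (natural log by default); unlike the
pair indices it is a true metric and degrades gracefully for nested
partitions, which contiguous genomic regions often are.

Association discoveries are scored from two points of view: the probe
POV compares the union of probes inside significant regions to the
probes inside true causal regions; the region POV counts a significant
estimated region as a true discovery when more than a fixed fraction
(default half) of its probes fall inside a single true causal region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import RegionPartition, ValidationError


@dataclass
class PartitionScore:
    rand: float
    adj_rand: float
    jaccard: float
    vi: float


@dataclass
class RecoveryScore:
    tpr_probe: float
    fdp_probe: float
    tpr_region: float
    fdp_region: float
    tpr_defined: bool = True


def _labels(part) -> np.ndarray:
    if isinstance(part, RegionPartition):
        return part.assignment
    return np.asarray(part, dtype=np.int64)


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    return table


def _comb2(x):
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def score_partition(estimate, truth, vi_base: float | None = None
                    ) -> PartitionScore:
    """Rand, adjusted Rand, Jaccard and VI between two labelings.

    ``vi_base`` rescales VI to that log base (default natural log, nats).
    """
    est = _labels(estimate)
    tru = _labels(truth)
    if est.shape != tru.shape:
        raise ValidationError("partitions must cover the same probes")
    N = _contingency(est, tru)
    total_pairs = _comb2(est.size)
    sum_ij = _comb2(N).sum()
    ai = N.sum(axis=1)
    bj = N.sum(axis=0)
    sum_i = _comb2(ai).sum()
    sum_j = _comb2(bj).sum()
    a = sum_ij
    b = sum_i - sum_ij
    c = sum_j - sum_ij
    d = total_pairs - a - b - c
    rand = (a + d) / total_pairs if total_pairs else 1.0
    jaccard = a / (a + b + c) if (a + b + c) else 1.0
    expected = sum_i * sum_j / total_pairs if total_pairs else 0.0
    denom = 0.5 * (sum_i + sum_j) - expected
    adj_rand = (sum_ij - expected) / denom if denom else 1.0
    # Variation of Information
    n = est.size
    pi = ai / n
    qj = bj / n
    h_p = -np.sum(pi * np.log(pi, where=pi > 0, out=np.zeros_like(pi)))
    h_q = -np.sum(qj * np.log(qj, where=qj > 0, out=np.zeros_like(qj)))
    nz = N > 0
    pij = N[nz] / n
    mi = np.sum(pij * np.log(pij / (np.outer(pi, qj)[nz])))
    vi = max(h_p + h_q - 2.0 * mi, 0.0)
    if vi_base is not None:
        vi /= np.log(vi_base)
    return PartitionScore(rand=float(rand), adj_rand=float(adj_rand),
                          jaccard=float(jaccard), vi=float(vi))


def score_recovery(significant_regions, estimate: RegionPartition,
                   truth_causal, truth: RegionPartition,
                   overlap_threshold: float = 0.5) -> RecoveryScore:
    """Probe-POV and region-POV TPR/FDP of significant estimated regions.

    ``significant_regions`` / ``truth_causal`` are sets of region labels
    in the estimated / true partitions.  With zero discoveries both FDPs
    are 0 by convention; with an empty causal truth TPR is undefined and
    returned as 0 with ``tpr_defined=False``.
    """
    if estimate.p != truth.p:
        raise ValidationError("partitions must cover the same probes")
    sig = set(int(g) for g in significant_regions)
    causal = set(int(g) for g in truth_causal)
    est = estimate.assignment
    tru = truth.assignment
    detected = np.isin(est, sorted(sig))
    causal_probes = np.isin(tru, sorted(causal))
    n_causal = int(causal_probes.sum())
    n_det = int(detected.sum())
    tp = int((detected & causal_probes).sum())
    tpr_defined = bool(causal)
    tpr_probe = tp / n_causal if n_causal else 0.0
    fdp_probe = (n_det - tp) / n_det if n_det else 0.0

    # region POV: an estimated region is a true discovery iff the fraction
    # of its probes inside a single causal true region exceeds the threshold
    hit_truth = set()
    n_true_disc = 0
    for g in sig:
        in_g = est == g
        size = int(in_g.sum())
        partners, counts = np.unique(tru[in_g], return_counts=True)
        best = -1
        best_frac = 0.0
        for partner, cnt in zip(partners, counts):
            if int(partner) in causal and cnt / size > best_frac:
                best_frac = cnt / size
                best = int(partner)
        if best_frac > overlap_threshold:
            n_true_disc += 1
            hit_truth.add(best)
    tpr_region = len(hit_truth) / len(causal) if causal else 0.0
    fdp_region = (len(sig) - n_true_disc) / len(sig) if sig else 0.0
    return RecoveryScore(tpr_probe=float(tpr_probe), fdp_probe=float(fdp_probe),
                         tpr_region=float(tpr_region),
                         fdp_region=float(fdp_region), tpr_defined=tpr_defined)
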