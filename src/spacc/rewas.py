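"""Region-based association scans with FDR control.

An (r)EWAS scan regresses a continuous response on each feature --
a region mean for rEWAS, a raw probe value for conventional EWAS --
with an intercept, and tests the slope with a two-sided t-test.
Multiplicity is handled by the Benjamini-Hochberg step-up rule at the
requested FDR level (the usual operating points are 1% and 5%).
Aggregating probes into regions first reduces the number of tests and
pools signal across correlated probes, which is the source of rEWAS's
power gain over probe-level EWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import ValidationError


@dataclass
class AssociationTable:
    """Per-feature univariate regression results.

    ``q_rank`` is the 1-based rank of each p-value (ascending);
    ``significant_at`` maps an FDR level to the boolean BH rejection
    vector; ``flagged`` marks zero-variance features (p forced to 1).
    """

    feature_id: np.ndarray
    coefficient: np.ndarray
    p_value: np.ndarray
    q_rank: np.ndarray
    flagged: np.ndarray
    significant_at: dict = field(default_factory=dict)

    def significant(self, fdr_level: float) -> np.ndarray:
        if fdr_level not in self.significant_at:
            self.significant_at[fdr_level] = bh_adjust(self.p_value, fdr_level)
        return self.significant_at[fdr_level]

    def significant_ids(self, fdr_level: float) -> list:
        return list(self.feature_id[self.significant(fdr_level)])


def univariate_scan(features: np.ndarray, y: np.ndarray,
                    feature_id=None,
                    fdr_levels=(0.01, 0.05)) -> AssociationTable:
    """OLS of y on (intercept, feature), one fit per column of ``features``.

    Missing feature cells are mean-imputed within the feature (a region
    mean missing for a subject is rare; the scan stays defined).
    Zero-variance features get p = 1 and are flagged.
    """
    F = np.array(features, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    y = np.asarray(y, dtype=float)
    n, G = F.shape
    if y.shape != (n,):
        raise ValidationError(f"response must have length n={n}")
    if n < 3:
        raise ValidationError("need n >= 3 subjects for a t-test")
    if np.isnan(y).any():
        raise ValidationError("response contains missing values")
    if np.isnan(F).any():
        col_mean = np.nanmean(F, axis=0)
        idx = np.where(np.isnan(F))
        F[idx] = np.take(col_mean, idx[1])
    if feature_id is None:
        feature_id = np.array([f"feature_{g + 1}" for g in range(G)],
                              dtype=object)
    feature_id = np.asarray(feature_id, dtype=object)

    yc = y - y.mean()
    Fc = F - F.mean(axis=0)
    sxx = (Fc ** 2).sum(axis=0)
    sxy = Fc.T @ yc
    syy = float((yc ** 2).sum())
    flagged = sxx <= 0
    safe_sxx = np.where(flagged, 1.0, sxx)
    slope = sxy / safe_sxx
    rss = np.maximum(syy - slope * sxy, 0.0)
    df = n - 2
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slope / np.sqrt(sigma2 / safe_sxx)
        bad = ~np.isfinite(tstat)
        tstat[bad] = np.sign(slope[bad]) * np.inf
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    pval = np.where(flagged, 1.0, pval)
    slope = np.where(flagged, 0.0, slope)
    order = np.argsort(pval, kind="stable")
    q_rank = np.empty(G, dtype=np.int64)
    q_rank[order] = np.arange(1, G + 1)
    table = AssociationTable(feature_id=feature_id, coefficient=slope,
                             p_value=pval, q_rank=q_rank, flagged=flagged)
    for level in fdr_levels:
        table.significant(level)
    return table


def bh_adjust(p_values, fdr_level: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection set at FDR level alpha.

    Rejects the k* smallest p-values where
    ``k* = max{k : p_(k) <= k * alpha / m}`` (inclusive at the boundary).
    Returns a boolean vector aligned with the input.
    """
    if not 0 < fdr_level < 1:
        raise ValidationError("fdr_level must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    m = p.size
    reject = np.zeros(m, dtype=bool)
    if m == 0:
        return reject
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ok = sorted_p <= fdr_level * np.arange(1, m + 1) / m
    if ok.any():
        k_star = int(np.flatnonzero(ok).max())
        reject[order[:k_star + 1]] = True
    return reject
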