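"""Domain types and I/O for probe-by-subject genomic matrices.

The central container is :class:`ProbeMatrix`: an ``n x p`` matrix of
real-valued measurements (methylation beta-values in (0,1) or CNV
log2-ratios) with per-probe genomic coordinates and a cell-level missing
mask.  Regions -- contiguous runs of probes fused across all subjects --
are represented by :class:`RegionPartition` and written as BED intervals.

Coordinate conventions: input positions are 1-based (array-manifest
convention); BED output is 0-based, half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("spacc")

MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


class SpaccError(Exception):
    """Base class for spacc errors."""


class ValidationError(SpaccError):
    """Raised when inputs violate a documented invariant."""


class FormatError(SpaccError):
    """Raised for malformed input files."""


def _natural_chrom_key(label: str):
    """Sort key placing chr2 before chr10 (numeric-aware, stable for odd labels)."""
    parts = re.split(r"(\d+)", str(label))
    return tuple(int(p) if p.isdigit() else p for p in parts)


# ---------------------------------------------------------------------------
# ProbeMatrix
# ---------------------------------------------------------------------------

@dataclass
class ProbeMatrix:
    """Probe-by-subject measurements with genomic metadata.

    Attributes
    ----------
    values : (n, p) float array
        Measurements; missing entries hold NaN.
    chrom, pos, probe_id : (p,) arrays
        Per-probe chromosome label, 1-based basepair position, identifier.
    missing_mask : (n, p) bool array
        True where the measurement is missing.
    subject_id : (n,) array of str
    data_kind : {"methylation", "cnv", None}
        Declared measurement type; methylation values are checked to lie
        in [0, 1].
    """

    values: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    probe_id: np.ndarray
    missing_mask: np.ndarray
    subject_id: np.ndarray
    data_kind: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-dimensional (subjects x probes)")
        n, p = self.values.shape
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.probe_id = np.asarray(self.probe_id, dtype=object)
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValidationError("missing_mask shape must match values")
        for name, arr in (("chrom", self.chrom), ("pos", self.pos),
                          ("probe_id", self.probe_id)):
            if arr.shape != (p,):
                raise ValidationError(f"{name} must have length p={p}")
        if self.subject_id.shape != (n,):
            raise ValidationError(f"subject_id must have length n={n}")
        if n < 1:
            raise ValidationError("need at least one subject")
        # values and mask must agree
        self.values = np.where(self.missing_mask, np.nan, self.values)
        self._validate_order()
        if self.data_kind == "methylation":
            obs = self.values[~self.missing_mask]
            if obs.size and (obs.min() < 0 or obs.max() > 1):
                raise ValidationError(
                    "methylation beta-values must lie in [0, 1]; "
                    f"observed range [{obs.min():.4g}, {obs.max():.4g}]")

    def _validate_order(self):
        for c in self.chromosomes():
            idx = np.flatnonzero(self.chrom == c)
            pos = self.pos[idx]
            if len(idx) < 2:
                continue
            d = np.diff(pos)
            if (d == 0).any():
                j = idx[int(np.flatnonzero(d == 0)[0])]
                raise ValidationError(
                    f"duplicate (chrom, pos) at {c!r}:{self.pos[j]}")
            if (d < 0).any():
                raise ValidationError(
                    f"probes on chromosome {c!r} are not position-sorted")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_arrays(cls, values, chrom, pos, probe_id=None, subject_id=None,
                    missing_mask=None, data_kind=None, sort=True):
        """Build a ProbeMatrix, sorting probes by (chrom, pos) if needed."""
        values = np.asarray(values, dtype=float)
        n, p = values.shape
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        if probe_id is None:
            probe_id = np.array([f"probe_{i + 1:06d}" for i in range(p)],
                                dtype=object)
        if subject_id is None:
            subject_id = np.array([f"subject_{i + 1:04d}" for i in range(n)],
                                  dtype=object)
        if missing_mask is None:
            missing_mask = np.isnan(values)
        missing_mask = np.asarray(missing_mask, dtype=bool)
        if sort:
            keys = [_natural_chrom_key(c) for c in chrom]
            order = sorted(range(p), key=lambda j: (keys[j], pos[j]))
            order = np.asarray(order)
            values = values[:, order]
            missing_mask = missing_mask[:, order]
            chrom = chrom[order]
            pos = pos[order]
            probe_id = np.asarray(probe_id, dtype=object)[order]
        labels, counts = np.unique(np.asarray(chrom, dtype=str),
                                   return_counts=True)
        if (counts < 2).any():
            bad = labels[counts < 2][0]
            raise ValidationError(
                f"chromosome {bad!r} has fewer than 2 probes")
        return cls(values=values, chrom=chrom, pos=pos, probe_id=probe_id,
                   missing_mask=missing_mask, subject_id=subject_id,
                   data_kind=data_kind)

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def chromosomes(self) -> list:
        """Chromosome labels in probe order (first appearance)."""
        seen, out = set(), []
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def select_probes(self, index) -> "ProbeMatrix":
        """Contiguous probe subset (no re-validation of p>=2 chrom rule)."""
        idx = (np.arange(self.p)[index] if isinstance(index, slice)
               else np.asarray(index))
        out = replace(
            self,
            values=self.values[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            probe_id=self.probe_id[idx],
            missing_mask=self.missing_mask[:, idx],
        )
        return out

    def split_chromosomes(self) -> list["ProbeMatrix"]:
        return [self.select_probes(np.flatnonzero(self.chrom == c))
                for c in self.chromosomes()]


# ---------------------------------------------------------------------------
# RegionPartition
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Contiguous grouping of probes into genomic regions.

    ``assignment[j]`` is the integer region label of probe ``j``; labels
    form contiguous runs ``0, 1, ..., G-1`` in probe order and never span
    chromosomes.  ``regions`` lists ``(chrom, start, stop)`` probe-index
    runs, half-open.
    """

    assignment: np.ndarray
    regions: list = field(default_factory=list)

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if self.assignment.ndim != 1 or self.assignment.size == 0:
            raise ValidationError("assignment must be a nonempty 1-d array")
        labels = self.assignment
        # contiguous runs with labels 0..G-1 in order
        change = np.flatnonzero(np.diff(labels) != 0)
        starts = np.concatenate([[0], change + 1])
        expected = np.repeat(np.arange(len(starts)),
                             np.diff(np.append(starts, labels.size)))
        if not np.array_equal(labels, expected):
            raise ValidationError(
                "assignment labels must be contiguous runs 0..G-1 in probe order")
        if not self.regions:
            stops = np.append(starts[1:], labels.size)
            self.regions = [(None, int(s), int(e)) for s, e in zip(starts, stops)]
        for (c, s, e) in self.regions:
            if e <= s:
                raise ValidationError("empty region in regions list")

    @property
    def n_regions(self) -> int:
        return int(self.assignment.max()) + 1

    @property
    def p(self) -> int:
        return self.assignment.size

    @classmethod
    def from_fused_gaps(cls, fused: np.ndarray, chrom=None) -> "RegionPartition":
        """Build from a boolean per-gap vector: True means probes i, i+1 fused."""
        fused = np.asarray(fused, dtype=bool)
        labels = np.concatenate([[0], np.cumsum(~fused)])
        part = cls(assignment=labels)
        if chrom is not None:
            part.attach_chrom(np.asarray(chrom, dtype=object))
        return part

    @classmethod
    def from_sizes(cls, sizes: Sequence[int], chrom=None) -> "RegionPartition":
        labels = np.repeat(np.arange(len(sizes)), sizes)
        part = cls(assignment=labels)
        if chrom is not None:
            part.attach_chrom(np.asarray(chrom, dtype=object))
        return part

    def attach_chrom(self, chrom: np.ndarray):
        """Record chromosome labels and check regions do not span chromosomes."""
        regions = []
        for (_, s, e) in self.regions:
            labels = set(chrom[s:e])
            if len(labels) > 1:
                raise ValidationError(
                    f"region [{s},{e}) spans chromosomes {sorted(map(str, labels))}")
            regions.append((chrom[s], s, e))
        self.regions = regions

    @staticmethod
    def concatenate(parts: Iterable["RegionPartition"]) -> "RegionPartition":
        parts = list(parts)
        assignment, regions, offset_label, offset_idx = [], [], 0, 0
        for part in parts:
            assignment.append(part.assignment + offset_label)
            for (c, s, e) in part.regions:
                regions.append((c, s + offset_idx, e + offset_idx))
            offset_label += part.n_regions
            offset_idx += part.p
        out = RegionPartition(assignment=np.concatenate(assignment))
        out.regions = regions
        return out


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tuning knobs for the fitting pipeline.

    Parameters
    ----------
    sigma_decay : float
        Per-basepair decay rate of the spatial fusion weights
        ``w_i = exp(-sigma_decay * d_i)``.  1e-5 suits CNV log-ratios
        (slow decay, long segments); 2e-4 suits methylation (fast decay,
        CpG-island-scale regions).
    weight_floor : float
        Weights below this are hard-thresholded to exactly zero, splitting
        the chain into independent subproblems.
    gamma : float or None
        Fusion penalty level; None means "select by cross-validation".
    tol, max_iter, nu : AMA solver controls (convergence tolerance,
        iteration cap, dual step size; nu <= 0.25 is always stable for the
        chain difference operator).
    outer_tol, outer_max_iter : missing-data MM outer-loop controls.
    k_folds : number of cross-validation folds.
    gamma_grid : explicit candidate gammas (strictly increasing), or None
        to build a log-spaced grid of ``n_gamma`` values ending at the
        adaptive full-fusion point.
    cv_tol, cv_max_iter, cv_outer_tol : looser solver controls used only
        inside cross-validation refits.
    seed : RNG seed for fold construction.
    """

    sigma_decay: float = 2e-4
    weight_floor: float = 1e-3
    gamma: float | None = None
    tol: float = 1e-6
    max_iter: int = 10000
    nu: float = 0.25
    outer_tol: float = 1e-7
    outer_max_iter: int = 100
    k_folds: int = 5
    gamma_grid: np.ndarray | None = None
    n_gamma: int = 50
    gamma_min_ratio: float = 1e-3
    cv_tol: float = 1e-3
    cv_max_iter: int = 2000
    cv_outer_tol: float = 1e-4
    sigma_method: str = "mad_data"
    seed: int = 0
    accelerate: bool = True

    def __post_init__(self):
        for name in ("sigma_decay", "tol", "nu", "outer_tol", "cv_tol",
                     "gamma_min_ratio"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.weight_floor < 0:
            raise ValidationError("weight_floor must be >= 0")
        if self.gamma is not None and self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if self.gamma_grid is not None:
            self.gamma_grid = np.asarray(self.gamma_grid, dtype=float)
            if (np.diff(self.gamma_grid) <= 0).any():
                raise ValidationError("gamma_grid must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_probe_matrix(path, data_kind: str | None = None) -> ProbeMatrix:
    """Read a tab-separated probe matrix.

    Expected header: ``chrom  pos  probe_id  <subject> ...`` with one row
    per probe; missing cells encoded as ``NA`` or empty.  Rows may appear
    in any order; probes are sorted by (chrom, pos) and exact duplicate
    (chrom, pos) rows are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=list(MISSING_TOKENS),
                     keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 4 or cols[0] != "chrom" or cols[1] != "pos" or cols[2] != "probe_id":
        raise FormatError(
            f"{path}: header must start with 'chrom\\tpos\\tprobe_id' followed "
            f"by at least one subject column; got {cols[:4]}")
    subjects = cols[3:]
    try:
        pos = df["pos"].astype(np.int64).to_numpy()
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer position: {exc}") from None
    meas = df[subjects]
    bad = meas.apply(lambda s: pd.to_numeric(s, errors="coerce"))
    with_value = meas.notna()
    unparsed = with_value & bad.isna()
    if unparsed.to_numpy().any():
        r, c = np.argwhere(unparsed.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric measurement {meas.iloc[r, c]!r} at probe "
            f"{df['probe_id'].iloc[r]!r}, subject {subjects[c]!r}")
    values = bad.to_numpy(dtype=float).T  # subjects x probes
    chrom = df["chrom"].to_numpy(dtype=object)
    dup = pd.DataFrame({"chrom": chrom, "pos": pos}).duplicated()
    if dup.any():
        j = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(f"{path}: duplicate (chrom, pos) = "
                              f"({chrom[j]!r}, {pos[j]})")
    return ProbeMatrix.from_arrays(
        values=values, chrom=chrom, pos=pos,
        probe_id=df["probe_id"].to_numpy(dtype=object),
        subject_id=np.asarray(subjects, dtype=object),
        data_kind=data_kind, sort=True)


def write_probe_matrix(probes: ProbeMatrix, path):
    """Write the TSV format accepted by :func:`read_probe_matrix`."""
    df = pd.DataFrame({"chrom": probes.chrom, "pos": probes.pos,
                       "probe_id": probes.probe_id})
    vals = np.where(probes.missing_mask, np.nan, probes.values)
    for i, s in enumerate(probes.subject_id):
        df[str(s)] = vals[i]
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def write_regions(partition: RegionPartition, probes: ProbeMatrix, path):
    """Write regions as BED: chrom, 0-based start, end, name, probe count."""
    if partition.p != probes.p:
        raise ValidationError(
            f"partition covers {partition.p} probes but matrix has {probes.p}")
    lines = []
    for g, (c, s, e) in enumerate(partition.regions):
        chrom = probes.chrom[s] if c is None else c
        start = int(probes.pos[s]) - 1          # 1-based -> 0-based
        end = int(probes.pos[e - 1])            # half-open end
        lines.append(f"{chrom}\t{start}\t{end}\tregion_{g + 1}\t{e - s}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_regions(path, probes: ProbeMatrix) -> RegionPartition:
    """Read a BED region file back into a partition over ``probes``.

    Probes are assigned to the region whose interval contains them; the
    intervals must tile the probes (every probe covered exactly once).
    """
    assignment = np.full(probes.p, -1, dtype=np.int64)
    with open(path) as fh:
        rows = [ln.split("\t") for ln in fh.read().splitlines() if ln.strip()]
    for g, row in enumerate(rows):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        inside = (probes.chrom == chrom) & (probes.pos - 1 >= start) & (probes.pos <= end)
        if (assignment[inside] != -1).any():
            raise ValidationError(f"{path}: overlapping region intervals")
        assignment[inside] = g
    if (assignment == -1).any():
        j = int(np.flatnonzero(assignment == -1)[0])
        raise ValidationError(
            f"{path}: probe {probes.probe_id[j]!r} not covered by any region")
    part = RegionPartition(assignment=assignment)
    part.attach_chrom(probes.chrom)
    return part


def region_means(probes: ProbeMatrix, partition: RegionPartition) -> np.ndarray:
    """Per-subject means over each region's non-missing probes, (n, G).

    Cells where every probe in the region is missing come back as NaN.
    These region-mean vectors are the reduced feature set used downstream
    (association scans, network estimation) in place of raw probe vectors.
    """
    if partition.p != probes.p:
        raise ValidationError(
            f"partition covers {partition.p} probes but matrix has {probes.p}")
    vals = np.where(probes.missing_mask, 0.0, probes.values)
    obs = (~probes.missing_mask).astype(float)
    G = partition.n_regions
    sums = np.zeros((probes.n, G))
    counts = np.zeros((probes.n, G))
    for g, (_, s, e) in enumerate(partition.regions):
        sums[:, g] = vals[:, s:e].sum(axis=1)
        counts[:, g] = obs[:, s:e].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    return means
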