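"""Expression normalization and gene filtering.

Implements TMM (trimmed mean of M-values) library-size normalization with
log2-CPM conversion, an expression-fraction filter for count data, an
inter-quartile-range filter for array-style intensities, and a deterministic
per-batch location-scale adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "FilterConfig",
    "tmm_normalize",
    "filter_expressed",
    "iqr_filter",
    "batch_adjust",
]


@dataclass
class CountMatrix:
    """Raw gene-level counts, genes in rows and samples in columns."""

    counts: pd.DataFrame
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dup[:5]}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dup[:5]}")
        if self.counts.shape[1] < 2:
            raise ValueError("CountMatrix requires at least 2 samples")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class ExpressionMatrix:
    """Normalized or measured expression values, genes × samples.

    ``unit`` is one of ``log2CPM``, ``log-intensity`` or ``adjusted``;
    ``provenance`` records the producing operation and its parameters.
    """

    values: pd.DataFrame
    unit: str = "log2CPM"
    cohort: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class FilterConfig:
    """Gene-retention thresholds.

    ``min_count`` is a strict lower bound (a sample "expresses" a gene when
    count > min_count); ``min_fraction`` is inclusive; genes with
    IQR < ``iqr_cutoff`` are excluded.
    """

    min_count: int = 1
    min_fraction: float = 0.20
    iqr_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in [0, 1]")
        if self.iqr_cutoff < 0:
            raise ValueError("iqr_cutoff must be >= 0")


def _choose_reference(counts: np.ndarray) -> int:
    """Pick the sample whose upper quartile is closest to the mean upper quartile."""
    uq = np.percentile(counts, 75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one library against the reference.

    Weighted trimmed mean of per-gene M-values with delta-method
    (inverse asymptotic variance) weights.
    """
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 0.0
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (
        lib_ref * ref[pos]
    )

    n = m.size
    lo_m, hi_m = int(np.floor(n * trim_m)) + 1, n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)) + 1, n - int(np.floor(n * trim_a))
    # rank-based double trim; ranks are 1-based, method="first" for determinism
    rank_m = pd.Series(m).rank(method="first").to_numpy()
    rank_a = pd.Series(a).rank(method="first").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    inv_w = 1.0 / w[keep]
    return float(np.sum(m[keep] * inv_w) / np.sum(inv_w))


def tmm_normalize(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> tuple[ExpressionMatrix, pd.Series]:
    """TMM scaling factors and log2-CPM conversion.

    Returns the log2CPM :class:`ExpressionMatrix` together with per-sample
    scaling factors (geometric mean 1).  log2CPM uses pseudocounts of 0.5 in
    the numerator and 1 on the effective library size::

        log2CPM = log2((count + 0.5) / (libsize * factor + 1) * 1e6)
    """
    mat = counts.counts.to_numpy(dtype=float)
    libsizes = mat.sum(axis=0)
    zero = np.flatnonzero(libsizes == 0)
    if zero.size:
        bad = counts.samples[zero[0]]
        raise ValueError(f"sample {bad!r} has zero total count")

    ref_idx = _choose_reference(mat)
    ref = mat[:, ref_idx]
    log2f = np.array(
        [
            _tmm_pair_factor(mat[:, j], ref, libsizes[j], libsizes[ref_idx], trim_m, trim_a)
            for j in range(mat.shape[1])
        ]
    )
    factors = 2.0**log2f
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1

    eff_lib = libsizes * factors
    log2cpm = np.log2((mat + 0.5) / (eff_lib + 1.0) * 1e6)
    fac = pd.Series(factors, index=counts.samples, name="tmm_factor")
    expr = ExpressionMatrix(
        values=pd.DataFrame(log2cpm, index=counts.genes, columns=counts.samples),
        unit="log2CPM",
        cohort=counts.cohort,
        provenance={
            "method": "tmm_normalize",
            "trim_m": trim_m,
            "trim_a": trim_a,
            "reference_sample": str(counts.samples[ref_idx]),
            "scaling_factors": {str(s): float(f) for s, f in fac.items()},
        },
    )
    return expr, fac


def filter_expressed(counts: CountMatrix, cfg: Optional[FilterConfig] = None) -> pd.Index:
    """Genes with count > min_count in at least min_fraction of samples."""
    cfg = cfg or FilterConfig()
    mat = counts.counts.to_numpy()
    frac = (mat > cfg.min_count).mean(axis=1)
    return counts.genes[frac >= cfg.min_fraction]


def iqr_filter(expr: ExpressionMatrix, cfg: Optional[FilterConfig] = None) -> pd.Index:
    """Genes whose inter-quartile range is at least ``iqr_cutoff``.

    Quartiles use linear interpolation.  Requires >= 4 samples.
    """
    cfg = cfg or FilterConfig()
    if expr.values.shape[1] < 4:
        raise ValueError("iqr_filter requires at least 4 samples")
    mat = expr.values.to_numpy(dtype=float)
    q75, q25 = np.percentile(mat, [75, 25], axis=1)
    return expr.genes[(q75 - q25) >= cfg.iqr_cutoff]


def batch_adjust(expr: ExpressionMatrix, batches) -> ExpressionMatrix:
    """Location-scale batch adjustment.

    Per gene and batch, centers and scales to the batch mean/sd, then
    restores the gene's pooled mean and pooled sd.  Batches with zero
    variance for a gene skip the scale step for that gene (warned once).
    """
    batches = pd.Series(np.asarray(batches), index=expr.samples)
    levels = batches.unique()
    if len(levels) < 2:
        raise ValueError("batch_adjust requires at least 2 batches")
    counts = batches.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batches with fewer than 2 samples: {small.index.tolist()}")

    mat = expr.values.to_numpy(dtype=float)
    pooled_mean = mat.mean(axis=1, keepdims=True)
    pooled_sd = mat.std(axis=1, ddof=0, keepdims=True)
    out = np.empty_like(mat)
    n_skipped = 0
    for lev in levels:
        cols = (batches == lev).to_numpy()
        sub = mat[:, cols]
        b_mean = sub.mean(axis=1, keepdims=True)
        b_sd = sub.std(axis=1, ddof=0, keepdims=True)
        zero_var = (b_sd == 0) | (pooled_sd == 0)
        n_skipped += int((b_sd == 0).sum())
        factor = np.where(zero_var, 1.0, pooled_sd / np.where(b_sd == 0, 1.0, b_sd))
        out[:, cols] = pooled_mean + (sub - b_mean) * factor
    if n_skipped:
        warnings.warn(
            f"batch_adjust: scale step skipped for {n_skipped} gene/batch "
            "combinations with zero variance"
        )
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=expr.genes, columns=expr.samples),
        unit="adjusted",
        cohort=expr.cohort,
        provenance={
            "method": "batch_adjust",
            "input_unit": expr.unit,
            "batches": {str(lev): int(counts[lev]) for lev in levels},
        },
    )
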