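"""Count normalization: TMM scale factors, CPM, replicate averaging.

The screen's expression currency is CPM (counts per million) after
between-sample normalization by the trimmed mean of M-values (TMM).
TMM assumes most genes are not differentially expressed: for each sample
it takes per-gene log2 expression ratios (M) against a reference sample,
double-trims by M and by average log abundance (A), and averages the
survivors with inverse-variance weights. The resulting per-sample factors
multiply library sizes, so a factor > 1 shrinks that sample's CPMs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import ExpressionMatrix, SampleMetadata, ValidationError

logger = logging.getLogger("channelscreen")


@dataclass(frozen=True)
class ScaleFactors:
    """Per-sample TMM scale factors, rescaled to geometric mean 1."""

    factors: pd.Series
    reference_sample_id: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("scale factors must be positive")
        gm = float(np.exp(np.mean(np.log(self.factors.to_numpy()))))
        if abs(gm - 1.0) > 1e-9:
            raise ValidationError(f"scale factors must have geometric mean 1, got {gm}")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference.

    Genes with a zero count in either sample are excluded pairwise. Trimming
    is rank-based on both the log-ratio M and the average log-abundance A;
    weights are the inverse of the binomial (delta-method) variance of M.
    """
    keep0 = (obs > 0) & (ref > 0)
    obs, ref = obs[keep0], ref[keep0]
    if obs.size == 0:
        logger.warning("TMM: no genes positive in both samples; factor set to 1")
        return 1.0
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        logger.warning("TMM: all genes trimmed away for a sample pair; factor set to 1")
        return 1.0
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / w[keep]
    f = float(np.sum(m[keep] * inv_w) / np.sum(inv_w))
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> ScaleFactors:
    """Compute TMM scale factors for every sample of a count matrix.

    The reference is the sample whose upper-quartile/library-size ratio is
    closest to the mean of that ratio across samples. Factors are rescaled
    so their geometric mean is exactly 1.
    """
    counts.require_unit("counts")
    y = counts.values.to_numpy(dtype=float)
    samples = counts.sample_ids
    if len(samples) < 2:
        raise ValidationError("TMM requires at least 2 samples")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        zero = [s for s, l in zip(samples, lib) if l == 0]
        raise ValidationError(f"samples with zero library size: {zero}")

    uq_ratio = np.quantile(y / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq_ratio - uq_ratio.mean())))
    ref = y[:, ref_idx]

    raw = np.array(
        [
            1.0
            if k == ref_idx
            else _tmm_pair(y[:, k], ref, lib[k], lib[ref_idx], trim_m, trim_a)
            for k in range(len(samples))
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return ScaleFactors(pd.Series(factors, index=samples, name="tmm_factor"),
                        reference_sample_id=samples[ref_idx])


def cpm(counts: ExpressionMatrix, factors: ScaleFactors | None = None) -> ExpressionMatrix:
    """Counts per million with optional TMM-adjusted library sizes.

    value = count / (library_size x factor) x 1e6. Without factors each
    column sums to exactly 1e6; with TMM factors a column sums to
    1e6 / factor.
    """
    counts.require_unit("counts")
    y = counts.values
    lib = y.sum(axis=0)
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise ValidationError(f"samples with zero library size: {zero}")
    if factors is not None:
        missing = set(y.columns) - set(factors.factors.index)
        if missing:
            raise ValidationError(f"no scale factor for samples {sorted(missing)}")
        lib = lib * factors.factors.reindex(y.columns)
    return ExpressionMatrix(y.div(lib, axis=1) * 1e6, "CPM")


def average_replicates(
    matrix: ExpressionMatrix, metadata: SampleMetadata
) -> ExpressionMatrix:
    """Collapse replicate columns to one column per isolate (arithmetic mean).

    The paper's cohorts carry 2-3 sequencing replicates per cell isolate;
    all downstream per-isolate statistics work on these averages. Isolate
    column order follows first appearance in the matrix.
    """
    metadata.check_matches(matrix)
    iso = metadata.isolates()
    order: list[str] = []
    cols: dict[str, list[str]] = {}
    for s in matrix.sample_ids:
        i = iso[s]
        if i not in cols:
            cols[i] = []
            order.append(i)
        cols[i].append(s)
    out = pd.DataFrame(
        {i: matrix.values[cols[i]].mean(axis=1) for i in order},
        index=matrix.values.index,
    )
    return ExpressionMatrix(out, matrix.unit)


def group_means(
    matrix: ExpressionMatrix, metadata: SampleMetadata, group: str
) -> pd.Series:
    """Per-gene mean over a group's isolate-averaged columns."""
    groups = metadata.isolate_groups()
    if group not in set(groups):
        raise ValidationError(f"unknown group {group!r}; metadata has {sorted(set(groups))}")
    averaged = average_replicates(matrix, metadata)
    members = [i for i in averaged.sample_ids if groups.get(i) == group]
    return averaged.values[members].mean(axis=1).rename(f"{group}_mean")
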