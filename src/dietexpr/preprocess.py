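"""Normalization, filtering, log transform, surrogate variable, batch removal.

Size factors follow the median-of-ratios rule (per-sample median of counts
divided by per-gene geometric means, over genes with all-positive counts).
The variance-stabilizing step is a shifted log of size-factor-normalized
counts — a documented stand-in for regularized-log transforms whose
gene-wise shrinkage is not reproducible from first principles. Hidden
structure beyond the known batch is captured by a single surrogate variable:
the first principal component of the residuals after regressing expression
on the protected factors (diet, tissue) and batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DesignInfo",
    "estimate_size_factors",
    "filter_low_counts",
    "filter_low_variance",
    "shifted_log_transform",
    "estimate_surrogate_variable",
    "remove_batch_effects",
]


@dataclass
class DesignInfo:
    """Known batch factor, one surrogate variable, and the protected factors."""

    meta: pd.DataFrame
    surrogate: pd.Series
    protected: tuple[str, ...] = ("diet", "tissue")
    batch_col: str = "batch"


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors s_j.

    s_j = median over usable genes of k_gj / geomean_g(k_g.), where usable
    genes have strictly positive counts in every sample.
    """
    k = counts.to_numpy(dtype=float)
    usable = (k > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene has all-positive counts; size factors undefined")
    ku = k[usable]
    log_gm = np.log(ku).mean(axis=1)
    s = np.exp(np.median(np.log(ku) - log_gm[:, None], axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def filter_low_counts(counts: pd.DataFrame, min_count: int = 10,
                      min_samples: int = 2) -> pd.DataFrame:
    """Keep genes with at least ``min_count`` reads in at least ``min_samples`` samples."""
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    if not keep.any():
        logger.warning("count filter removed every gene")
    logger.info("count filter: %d -> %d genes", len(counts), int(keep.sum()))
    return counts.loc[keep]


def filter_low_variance(matrix: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Keep rows whose sample variance (n-1 denominator) is >= threshold."""
    keep = matrix.var(axis=1, ddof=1) >= threshold
    logger.info("variance filter: %d -> %d rows", len(matrix), int(keep.sum()))
    return matrix.loc[keep]


def shifted_log_transform(counts: pd.DataFrame, sizefactors: pd.Series,
                          pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(k_gj / s_j + pseudocount); provenance recorded in ``attrs``."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    expr = np.log2(counts / sizefactors.reindex(counts.columns) + pseudocount)
    expr.attrs["provenance"] = "raw-log"
    return expr


def _design_matrix(meta: pd.DataFrame, factors) -> np.ndarray:
    cols = [np.ones(len(meta))]
    for f in factors:
        levels = pd.unique(meta[f])
        for lev in levels[1:]:
            cols.append((meta[f] == lev).to_numpy(float))
    return np.column_stack(cols)


def estimate_surrogate_variable(expr: pd.DataFrame, meta: pd.DataFrame,
                                protected: tuple[str, ...] = ("diet", "tissue"),
                                batch_col: str = "batch") -> DesignInfo:
    """One surrogate variable from residual PCA.

    Regresses each gene on protected factors plus batch, then takes the first
    right singular vector of the gene x sample residual matrix as the
    surrogate, standardized to zero mean and unit norm. Returns a zero vector
    with a warning when residuals vanish.
    """
    meta = meta.set_index("sample_id").loc[list(expr.columns)].reset_index()
    factors = [f for f in (*protected, batch_col) if meta[f].nunique() > 1]
    X = _design_matrix(meta, factors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design for surrogate-variable estimation")
    if expr.shape[1] < X.shape[1] + 2:
        raise ValueError("need at least 2 more samples than design columns")
    Y = expr.to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    scale = np.linalg.norm(Y) + 1e-300
    if np.linalg.norm(resid) < 1e-10 * scale:
        logger.warning("residual matrix is numerically zero; surrogate undefined")
        sv = np.zeros(expr.shape[1])
    else:
        _, _, vt = np.linalg.svd(resid, full_matrices=False)
        sv = vt[0]
        sv = sv - sv.mean()
        nrm = np.linalg.norm(sv)
        sv = sv / nrm if nrm > 0 else sv
        nz = np.nonzero(sv)[0]
        if nz.size and sv[nz[0]] < 0:  # deterministic sign
            sv = -sv
    return DesignInfo(meta=meta,
                      surrogate=pd.Series(sv, index=expr.columns, name="SV"),
                      protected=tuple(f for f in protected if meta[f].nunique() > 1),
                      batch_col=batch_col)


def remove_batch_effects(expr: pd.DataFrame, design_info: DesignInfo) -> pd.DataFrame:
    """Subtract fitted batch and surrogate components, protecting diet/tissue.

    Per gene, least squares on [protected | batch | SV]; only the batch and
    SV components are removed, so protected-factor group structure is kept.
    """
    meta = design_info.meta.set_index("sample_id").loc[list(expr.columns)].reset_index()
    Xp = _design_matrix(meta, design_info.protected)
    batch_cols = []
    levels = pd.unique(meta[design_info.batch_col])
    for lev in levels[1:]:
        batch_cols.append((meta[design_info.batch_col] == lev).to_numpy(float))
    Xb = np.column_stack(batch_cols) if batch_cols else np.empty((len(meta), 0))
    sv = design_info.surrogate.reindex(expr.columns).to_numpy(float)
    use_sv = np.linalg.norm(sv) > 0
    Xs = sv[:, None] if use_sv else np.empty((len(meta), 0))
    X = np.hstack([Xp, Xb, Xs])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch is confounded with a protected factor")
    Y = expr.to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    nuis = slice(Xp.shape[1], X.shape[1])
    corrected = Y - (X[:, nuis] @ beta[nuis]).T
    out = pd.DataFrame(corrected, index=expr.index, columns=expr.columns)
    out.attrs["provenance"] = "batch-corrected"
    return out
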