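"""Quality control and normalization of raw UMI count matrices.

The pipeline mirrors the conventional single-cell toolchain: discard cells
with too few expressed genes or excessive mitochondrial content, depth
normalize each cell, log-transform, and z-score each gene.  Rank-based
statistics downstream are invariant to any per-cell monotone normalization
applied uniformly, so the exact recipe mostly matters for the regression
engine, which expects a scaled (zero-mean) matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

from .io import (
    LAYER_NORMALIZED,
    LAYER_RAW,
    LAYER_SCALED,
    ExpressionMatrix,
)

logger = logging.getLogger(__name__)

DEFAULT_MITO_PREFIXES = ("MT-", "mt-")


def qc_filter(
    m: ExpressionMatrix,
    mito_prefix: tuple[str, ...] | str = DEFAULT_MITO_PREFIXES,
    min_genes: int = 500,
    max_mito_frac: float = 0.10,
) -> ExpressionMatrix:
    """Remove low-quality cells from a raw count matrix.

    A cell is kept iff it expresses at least ``min_genes`` genes (nonzero
    counts) and at most ``max_mito_frac`` of its reads map to mitochondrial
    genes (identified by name prefix).  Both bounds are inclusive: the
    removal rule uses strict inequalities, so a cell at exactly 500 genes
    and 10% mitochondrial reads is retained.  The gene axis is unchanged.
    """
    if m.layer_tag != LAYER_RAW:
        raise ValueError("qc_filter expects raw counts")
    if isinstance(mito_prefix, str):
        mito_prefix = (mito_prefix,)
    vals = m.values
    if sp.issparse(vals):
        expressed = np.asarray((vals > 0).sum(axis=1)).ravel()
        totals = np.asarray(vals.sum(axis=1)).ravel()
    else:
        vals = np.asarray(vals)
        expressed = (vals > 0).sum(axis=1)
        totals = vals.sum(axis=1)
    mito_mask = np.array(
        [any(str(g).startswith(p) for p in mito_prefix) for g in m.gene_ids]
    )
    if mito_mask.any():
        sub = vals[:, mito_mask]
        mito_counts = np.asarray(sub.sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
    keep = (expressed >= min_genes) & (mito_frac <= max_mito_frac)
    n_before, n_after = m.n_cells, int(keep.sum())
    logger.info("qc_filter: %d cells before, %d after", n_before, n_after)
    if n_after == 0:
        raise ValueError(
            "qc_filter removed every cell; review min_genes/max_mito_frac "
            "thresholds against this dataset"
        )
    return m.subset_cells(keep)


def normalize_and_scale(
    m: ExpressionMatrix,
    scale_factor: float = 1e4,
    depth_normalize: bool = True,
    log_transform: bool = True,
    regress_covariates: bool = True,
    zscore: bool = True,
    mito_prefix: tuple[str, ...] | str = DEFAULT_MITO_PREFIXES,
) -> ExpressionMatrix:
    """Depth-normalize, log1p, regress out cell covariates, z-score.

    Each cell is rescaled to ``scale_factor`` total counts and log1p
    transformed; each gene is then regressed on per-cell technical
    covariates (log total UMI count, plus mitochondrial fraction when
    mito genes are present) and replaced by its residuals, and finally
    centered to mean zero and unit variance across cells; zero-variance
    genes become all-zero columns.  The covariate regression matters:
    cells with shallow sequencing carry extra dropout zeros in every
    gene, which otherwise couples all genes through a shared depth
    component and inflates coincidental enrichments.  The raw count
    matrix stays attached as ``.raw`` so dropout (zero raw count)
    queries remain possible on the scaled result.
    """
    if m.layer_tag != LAYER_RAW:
        raise ValueError("normalize_and_scale expects raw counts")
    if isinstance(mito_prefix, str):
        mito_prefix = (mito_prefix,)
    x = m.dense().astype(float)
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = m.cell_ids[totals == 0][0]
        raise ValueError(
            f"cell {bad!r} has zero total count; run qc_filter first"
        )
    if depth_normalize:
        x = x / totals[:, None] * scale_factor
    if log_transform:
        x = np.log1p(x)
    if regress_covariates and x.shape[0] > 2:
        covs = [np.log(totals)]
        mito_mask = np.array(
            [any(str(g).startswith(p) for p in mito_prefix)
             for g in m.gene_ids]
        )
        if mito_mask.any():
            covs.append(
                np.asarray(m.dense()[:, mito_mask].sum(axis=1)) / totals
            )
        C = np.column_stack([np.ones(x.shape[0])] + covs)
        beta, *_ = np.linalg.lstsq(C, x, rcond=None)
        x = x - C @ beta
    tag = LAYER_NORMALIZED
    if zscore:
        mu = x.mean(axis=0)
        # sample sd (ddof=1), the convention of the standard toolchain
        sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
        nonconst = sd > 0
        x = x - mu[None, :]
        x[:, nonconst] /= sd[None, nonconst]
        x[:, ~nonconst] = 0.0
        tag = LAYER_SCALED
    raw = ExpressionMatrix(m.values, m.cell_ids, m.gene_ids, LAYER_RAW)
    return ExpressionMatrix(x, m.cell_ids, m.gene_ids, tag, raw=raw)
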