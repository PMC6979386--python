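"""Dropout-aware robust rank aggregation for single-cell CRISPR screens.

Cells are ranked by a marker gene's (or signature's) expression; for each
perturbation target the ranks of its cells are converted to percentiles,
whose order statistics follow Beta(k, n+1-k) under the null of uniform
placement.  The enrichment score rho is the minimum order-statistic
p-value, truncated to respect dropout: for positive selection (target
cells pushed toward high marker expression) only the j cells with nonzero
raw marker counts contribute; for negative selection the ranking is
ascending, the j zero-count cells sit at the front and are excluded.
Significance comes from permuting the guide assignment labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc

from .io import CellIdentity, ExpressionMatrix
from .phenotype import signature_score
from .significance import PermutationPlan, benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class CellRanking:
    """A full ranking of cells by marker expression.

    ``ranks[i]`` is the 1-based rank of cell ``cell_ids[i]``; descending
    direction puts the highest expression at rank 1.  ``zero_flags`` marks
    cells whose RAW marker count is zero (dropout candidates); ``alpha``
    is the fraction of cells with nonzero raw counts.
    """

    marker_id: str
    direction: str
    ranks: np.ndarray
    zero_flags: np.ndarray
    cell_ids: np.ndarray

    @property
    def M(self) -> int:
        return len(self.ranks)

    @property
    def alpha(self) -> float:
        return float((~self.zero_flags).mean())


@dataclass
class RRAResult:
    """Per (target, marker) rank-aggregation outcome."""

    target_id: str
    marker_id: str
    rho_neg: float
    rho_pos: float
    p_neg: float
    p_pos: float
    fdr_neg: float
    fdr_pos: float
    score: float
    n_cells: int
    n_nonzero: int


def rank_cells(
    scaled: ExpressionMatrix,
    raw: ExpressionMatrix | None,
    marker,
    direction: str = "descending",
) -> CellRanking:
    """Rank all cells by a marker gene or signature.

    ``marker`` is a gene symbol or a ``(name, [genes])`` pair; signature
    values are per-cell means of the scaled member columns, and a cell's
    zero flag is set only when every member's raw count is zero.  Ties are
    broken deterministically by barcode lexicographic order.
    """
    if direction not in ("descending", "ascending"):
        raise ValueError(f"unknown direction {direction!r}")
    if raw is None:
        raw = scaled.raw
    if raw is None:
        raise ValueError("raw count matrix required for dropout flags")
    if isinstance(marker, str):
        values = scaled.column(marker)
        zero = raw.column(marker) == 0
        marker_id = marker
    else:
        marker_id, genes = marker
        values = signature_score(scaled, genes)
        present = [g for g in genes if g in set(scaled.gene_ids)]
        raw_sub = np.column_stack([raw.column(g) for g in present])
        zero = (raw_sub == 0).all(axis=1)
    bc_order = np.argsort(np.argsort(scaled.cell_ids.astype(str), kind="stable"))
    key = -values if direction == "descending" else values
    order = np.lexsort((bc_order, key))
    ranks = np.empty(len(values), dtype=np.int64)
    ranks[order] = np.arange(1, len(values) + 1)
    return CellRanking(marker_id, direction, ranks, np.asarray(zero), scaled.cell_ids)


def order_statistic_pvalues(u) -> np.ndarray:
    """Beta order-statistic p-values for sorted percentiles.

    For sorted u_(1) <= ... <= u_(n) in [0,1], returns
    p_k = P(Beta(k, n+1-k) <= u_(k)), the probability that the kth
    smallest of n uniforms falls at or below u_(k) (equivalently the
    binomial tail P(Binom(n, u_(k)) >= k)).
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("u must be a non-empty 1-D array")
    if np.any((u < 0) | (u > 1)):
        raise ValueError("percentiles must lie in [0, 1]")
    if np.any(np.diff(u) < 0):
        raise ValueError("percentiles must be sorted ascending")
    n = u.size
    k = np.arange(1, n + 1)
    return betainc(k, n + 1 - k, u)


def _resolve_indices(ranking: CellRanking, target_cells) -> np.ndarray:
    arr = np.asarray(target_cells)
    if arr.size == 0:
        raise ValueError("target cell subset is empty")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.int64)
    lookup = {str(c): i for i, c in enumerate(ranking.cell_ids)}
    try:
        return np.array([lookup[str(c)] for c in arr], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"cell {exc.args[0]!r} not in ranking") from None


def rho_positive(ranking: CellRanking, target_cells) -> tuple[float, int]:
    """Minimum order-statistic p-value over the j nonzero target cells.

    Requires a descending ranking (high marker expression first).  Cells
    with zero raw marker count carry no evidence of high expression and
    are truncated away; with j = 0 the score is 1.
    """
    idx = _resolve_indices(ranking, target_cells)
    u = np.sort(ranking.ranks[idx] / ranking.M)
    j = int((~ranking.zero_flags[idx]).sum())
    if j == 0:
        return 1.0, 0
    p = order_statistic_pvalues(u)
    return float(p[:j].min()), j


def rho_negative(ranking_asc: CellRanking, target_cells) -> tuple[float, int]:
    """Minimum order-statistic p-value excluding the j dropout cells.

    Requires an ascending ranking (lowest marker expression first), where
    zero-count cells occupy the front of the list; those first j order
    statistics are excluded.  With j = n the score is 1.
    """
    idx = _resolve_indices(ranking_asc, target_cells)
    u = np.sort(ranking_asc.ranks[idx] / ranking_asc.M)
    j = int(ranking_asc.zero_flags[idx].sum())
    if j == len(idx):
        return 1.0, j
    p = order_statistic_pvalues(u)
    return float(p[j:].min()), j


def selection_score(
    p_neg: float, p_pos: float, floor: float | None = None
) -> float:
    """Signed log-p summary combining both selection directions.

    Natural log of the smaller p-value, negative when negative selection
    wins (perturbation lowers the marker), positive when positive
    selection wins; zero on a tie.  ``floor`` clamps zero p-values to the
    permutation resolution 1/(n_perm+1).
    """
    if floor is not None:
        p_neg = max(p_neg, floor)
        p_pos = max(p_pos, floor)
    if p_neg < p_pos:
        return math.log(p_neg)
    if p_pos < p_neg:
        return -math.log(p_pos)
    return 0.0


def _rho_batch(
    rank_d: np.ndarray,
    rank_a: np.ndarray,
    zero: np.ndarray,
    idx: np.ndarray,
    M: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized rho for a (batch, group, n) block of cell-index sets."""
    n = idx.shape[-1]
    k = np.arange(1, n + 1)
    a, b = k.astype(float), (n + 1 - k).astype(float)
    z = zero[idx]
    u_d = np.sort(rank_d[idx], axis=-1) / M
    p_d = betainc(a, b, u_d)
    j_nz = n - z.sum(axis=-1)
    rho_pos = np.where(k <= j_nz[..., None], p_d, 1.0).min(axis=-1)
    u_a = np.sort(rank_a[idx], axis=-1) / M
    p_a = betainc(a, b, u_a)
    j_z = z.sum(axis=-1)
    rho_neg = np.where(k > j_z[..., None], p_a, 1.0).min(axis=-1)
    return rho_pos, rho_neg


def rra_test(
    scaled: ExpressionMatrix,
    raw: ExpressionMatrix | None,
    marker,
    identity: CellIdentity,
    n_perm: int = 1000,
    seed: int = 0,
    chunk: int = 200,
) -> list[RRAResult]:
    """Rank-aggregation test of every target against one marker.

    Observed rho values (both directions) are compared to ``n_perm``
    label permutations in which each cell's guide bundle is reassigned to
    a random cell, preserving per-target cell counts.  Empirical p-values
    use the add-one estimator; BH adjustment runs across targets within
    each direction; the selection score combines the two permutation
    p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    present = set(scaled.cell_ids.astype(str))
    id_cells = set(identity.cells().astype(str))
    keep = np.array([str(c) in id_cells for c in scaled.cell_ids])
    if not keep.any():
        raise ValueError("no overlap between matrix cells and identity cells")
    sub = scaled.subset_cells(keep)
    sub_raw = raw.subset_cells(keep) if raw is not None else None
    identity = identity.subset_cells(present)

    if (identity.moi() > 1).any():
        logger.warning(
            "cells with multiple targets present: rank aggregation is not "
            "suited to high-MOI screens; each such cell contributes to every "
            "target it carries"
        )

    ranking_d = rank_cells(sub, sub_raw, marker, "descending")
    ranking_a = rank_cells(sub, sub_raw, marker, "ascending")
    M = ranking_d.M
    pos_of = {str(c): i for i, c in enumerate(sub.cell_ids)}

    targets = identity.targets(include_ntc=False)
    if not targets:
        raise ValueError("identity table has no targeting entries")
    target_idx = {
        t: np.array([pos_of[str(c)] for c in identity.cells_for_target(t)],
                    dtype=np.int64)
        for t in targets
    }

    # group targets by cell-set size so rho is computed in vector batches
    groups: dict[int, list[str]] = {}
    for t in targets:
        groups.setdefault(len(target_idx[t]), []).append(t)

    obs_pos: dict[str, float] = {}
    obs_neg: dict[str, float] = {}
    counts_pos = {t: 0 for t in targets}
    counts_neg = {t: 0 for t in targets}
    n_nonzero = {}
    ident = np.arange(M)[None, :]
    plan = PermutationPlan(n_perm=n_perm, seed=seed)

    group_idx = {}
    for n, ts in groups.items():
        gi = np.stack([target_idx[t] for t in ts])  # (G, n)
        group_idx[n] = (ts, gi)
        rp, rn = _rho_batch(ranking_d.ranks, ranking_a.ranks,
                            ranking_d.zero_flags, ident[:, gi][0], M)
        for g, t in enumerate(ts):
            obs_pos[t] = float(rp[g])
            obs_neg[t] = float(rn[g])
            n_nonzero[t] = int((~ranking_d.zero_flags[gi[g]]).sum())

    for start in range(0, n_perm, chunk):
        rounds = range(start, min(start + chunk, n_perm))
        perms = np.stack([plan.permutation(M, r) for r in rounds])
        for n, (ts, gi) in group_idx.items():
            idx = perms[:, gi]  # (B, G, n)
            rp, rn = _rho_batch(ranking_d.ranks, ranking_a.ranks,
                                ranking_d.zero_flags, idx, M)
            for g, t in enumerate(ts):
                counts_pos[t] += int((rp[:, g] <= obs_pos[t]).sum())
                counts_neg[t] += int((rn[:, g] <= obs_neg[t]).sum())

    p_pos = np.array([(1 + counts_pos[t]) / (1 + n_perm) for t in targets])
    p_neg = np.array([(1 + counts_neg[t]) / (1 + n_perm) for t in targets])
    fdr_pos = benjamini_hochberg(p_pos)
    fdr_neg = benjamini_hochberg(p_neg)

    marker_id = marker if isinstance(marker, str) else marker[0]
    results = []
    for i, t in enumerate(targets):
        results.append(
            RRAResult(
                target_id=t,
                marker_id=marker_id,
                rho_neg=obs_neg[t],
                rho_pos=obs_pos[t],
                p_neg=float(p_neg[i]),
                p_pos=float(p_pos[i]),
                fdr_neg=float(fdr_neg[i]),
                fdr_pos=float(fdr_pos[i]),
                score=selection_score(float(p_neg[i]), float(p_pos[i]),
                                      floor=plan.floor),
                n_cells=len(target_idx[t]),
                n_nonzero=n_nonzero[t],
            )
        )
    return results


def rra_table(results: list[RRAResult]) -> pd.DataFrame:
    """Flatten results into the tabular export layout."""
    return pd.DataFrame(
        [
            {
                "target": r.target_id,
                "marker": r.marker_id,
                "n_cells": r.n_cells,
                "n_nonzero": r.n_nonzero,
                "rho_neg": r.rho_neg,
                "rho_pos": r.rho_pos,
                "p_neg": r.p_neg,
                "p_pos": r.p_pos,
                "fdr_neg": r.fdr_neg,
                "fdr_pos": r.fdr_pos,
                "score": r.score,
            }
            for r in results
        ]
    )
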