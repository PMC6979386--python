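"""Ridge-regression estimation of perturbation effects on all genes.

The scaled expression matrix Y (M cells x N genes) is regressed on the
binary cell identity design D (M x K targets): Y = D S + eps, solved in
closed form as S = (D'D + lambda I)^{-1} D'Y.  Because each cell can
carry several guides, the regression deconvolves the effects of targets
that co-occur within cells — the property that makes this engine usable
on high-MOI screens.  Significance again comes from permuting the
correspondence between identity rows and expression rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .io import CellIdentity, ExpressionMatrix
from .phenotype import signature_score
from .significance import PermutationPlan, benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """M x K binary matrix; entry (j, X) is 1 iff cell j carries target X."""

    values: np.ndarray
    target_ids: list[str]
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("design entries must be 0/1")
        if v.shape != (len(self.cell_ids), len(self.target_ids)):
            raise ValueError("design shape does not match labels")
        self.values = v.astype(float)


@dataclass
class ScoreMatrix:
    """K targets x N genes selection scores with matched p-values/FDRs.

    ``fdrs`` adjusts each target's row across genes (transcriptome scan
    of one perturbation); the per-marker column family used when scanning
    a phenotype is computed on demand by :func:`query_marker`.
    """

    scores: np.ndarray
    pvals: np.ndarray
    fdrs: np.ndarray
    target_ids: list[str]
    gene_ids: np.ndarray
    lam: float
    n_perm: int

    def frame(self, which: str = "scores") -> pd.DataFrame:
        mat = getattr(self, which)
        return pd.DataFrame(mat, index=self.target_ids, columns=self.gene_ids)

    def long_format(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.target_ids):
            for j, g in enumerate(self.gene_ids):
                rows.append((t, g, self.scores[i, j], self.pvals[i, j],
                             self.fdrs[i, j]))
        return pd.DataFrame(rows, columns=["target", "gene", "score", "p", "fdr"])

    def write(self, prefix: str) -> None:
        for which in ("scores", "pvals", "fdrs"):
            self.frame(which).to_csv(f"{prefix}.{which}.tsv", sep="\t")


def build_design_matrix(
    identity: CellIdentity,
    cells,
    include_ntc_column: bool = True,
) -> DesignMatrix:
    """Binary design from the identity table over an ordered cell list.

    Targets occupy sorted-order columns with the non-targeting control
    pseudo-target last (when included); cells with no assignment are
    excluded with a logged count.
    """
    cells = np.asarray(cells, dtype=object)
    targets = identity.targets(include_ntc=False)
    if include_ntc_column and (
        identity.assignments["target"] == identity.ntc_label
    ).any():
        targets = targets + [identity.ntc_label]
    col_of = {t: i for i, t in enumerate(targets)}
    cell_targets = identity.assignments.groupby("cell")["target"].apply(set)
    rows, kept = [], []
    dropped = 0
    for c in cells:
        ts = cell_targets.get(str(c))
        if ts is None:
            dropped += 1
            continue
        row = np.zeros(len(targets))
        for t in ts:
            if t in col_of:
                row[col_of[t]] = 1.0
        if row.sum() == 0 and not include_ntc_column:
            # control-only cell kept with an all-zero row: the intercept-free
            # model then treats controls as the baseline
            pass
        rows.append(row)
        kept.append(c)
    if dropped:
        logger.info("build_design_matrix: %d cells had no assignment", dropped)
    if not rows:
        raise ValueError("no cell in the list has an identity assignment")
    return DesignMatrix(np.vstack(rows), targets, np.asarray(kept, dtype=object))


def _solve(A: np.ndarray, B: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    try:
        c, low = sla.cho_factor(A)
        return sla.cho_solve((c, low), B)
    except np.linalg.LinAlgError:
        c, low = sla.cho_factor(A + jitter * np.eye(A.shape[0]))
        return sla.cho_solve((c, low), B)


def ridge_solve(
    D: DesignMatrix, Y: ExpressionMatrix | np.ndarray, lam: float = 0.01
) -> np.ndarray:
    """Closed-form ridge solution S = (D'D + lambda I)^{-1} D'Y."""
    Ymat = Y.dense() if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    Dv = D.values
    if Dv.shape[0] != Ymat.shape[0]:
        raise ValueError(
            f"design has {Dv.shape[0]} cells but expression has {Ymat.shape[0]}"
        )
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    K = Dv.shape[1]
    A = Dv.T @ Dv + lam * np.eye(K)
    if lam == 0:
        rank = np.linalg.matrix_rank(A)
        if rank < K:
            # name a collinear pair to make the error actionable
            _, r = np.linalg.qr(Dv)
            dep = [D.target_ids[i] for i in range(K) if abs(r[i, i]) < 1e-10]
            raise np.linalg.LinAlgError(
                f"singular design at lambda=0; collinear columns include {dep}"
            )
        return np.linalg.solve(A, Dv.T @ Ymat)
    return _solve(A, Dv.T @ Ymat)


def lr_test(
    D: DesignMatrix,
    Y: ExpressionMatrix | np.ndarray,
    lam: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    sided: str = "two_sided_abs",
    gene_ids=None,
) -> ScoreMatrix:
    """Ridge scores with permutation p-values and per-row BH FDR.

    Each permutation round applies one global shuffle of the expression
    rows against the identity rows (MOI structure and column sums are
    untouched, and D'D — hence the factorization — is permutation
    invariant), recomputes S, and updates per-entry exceedance counts.
    Two-sided p-values on |s| by default; ``sided="ge"``/``"le"`` give
    one-sided alternatives.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(Y, ExpressionMatrix):
        if gene_ids is None:
            gene_ids = Y.gene_ids
        Ymat = Y.dense()
    else:
        Ymat = np.asarray(Y, float)
        if gene_ids is None:
            gene_ids = np.array([f"g{j}" for j in range(Ymat.shape[1])],
                                dtype=object)
    Dv = D.values
    K = Dv.shape[1]
    floor = 1.0 / (n_perm + 1)
    if floor * Ymat.shape[1] > 0.05:
        logger.warning(
            "n_perm=%d gives p-value floor %.3g; FDR resolution across %d "
            "genes may be limited", n_perm, floor, Ymat.shape[1]
        )
    A = Dv.T @ Dv + lam * np.eye(K)
    c, low = sla.cho_factor(A)
    DtY = Dv.T @ Ymat
    S = sla.cho_solve((c, low), DtY)

    plan = PermutationPlan(n_perm=n_perm, seed=seed)
    counts = np.zeros_like(S)
    absS = np.abs(S)
    for r in range(n_perm):
        perm = plan.permutation(Ymat.shape[0], r)
        Sp = sla.cho_solve((c, low), Dv.T @ Ymat[perm])
        if sided == "two_sided_abs":
            counts += np.abs(Sp) >= absS
        elif sided == "ge":
            counts += Sp >= S
        elif sided == "le":
            counts += Sp <= S
        else:
            raise ValueError(f"unknown sidedness {sided!r}")
    pvals = (1 + counts) / (1 + n_perm)
    fdrs = np.vstack([benjamini_hochberg(pvals[i]) for i in range(K)])
    return ScoreMatrix(S, pvals, fdrs, list(D.target_ids),
                       np.asarray(gene_ids, dtype=object), lam, n_perm)


def query_marker(sm: ScoreMatrix, marker: str) -> pd.DataFrame:
    """Phenotype scan: all targets' effects on one marker gene.

    Returns (target, score, p, fdr) sorted by score descending with
    stable target-id tiebreak; the FDR here is BH across the K targets
    of this marker's column.
    """
    idx = np.flatnonzero(sm.gene_ids == marker)
    if len(idx) == 0:
        raise KeyError(f"marker {marker!r} not in score matrix")
    j = int(idx[0])
    col_fdr = benjamini_hochberg(sm.pvals[:, j])
    df = pd.DataFrame(
        {
            "target": sm.target_ids,
            "score": sm.scores[:, j],
            "p": sm.pvals[:, j],
            "fdr": col_fdr,
        }
    )
    return (
        df.sort_values(["score", "target"], ascending=[False, True],
                       kind="stable")
        .reset_index(drop=True)
    )


def center_by_ntc(Y: ExpressionMatrix, identity: CellIdentity) -> ExpressionMatrix:
    """Alternative control handling: subtract each gene's mean over
    control-only cells instead of carrying an NTC design column."""
    ntc_cells = set(map(str, identity.control_only_cells()))
    mask = np.array([str(c) in ntc_cells for c in Y.cell_ids])
    if not mask.any():
        raise ValueError("no control-only cells to center on")
    vals = Y.dense() - Y.dense()[mask].mean(axis=0, keepdims=True)
    return ExpressionMatrix(vals, Y.cell_ids, Y.gene_ids, Y.layer_tag, raw=Y.raw)


def append_signature_column(
    Y: ExpressionMatrix, name: str, genes
) -> ExpressionMatrix:
    """Append a per-cell signature score as a pseudo-gene column of Y."""
    score = signature_score(Y, genes)
    vals = np.column_stack([Y.dense(), score])
    return ExpressionMatrix(
        vals,
        Y.cell_ids,
        np.concatenate([Y.gene_ids, np.array([name], dtype=object)]),
        Y.layer_tag,
        raw=Y.raw,
    )
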