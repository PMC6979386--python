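"""Readers and writers for single-cell CRISPR screen inputs.

Supported formats: MatrixMarket coordinate triplets with sibling
features/barcodes files (10x dialect), dense delimited text, sgRNA cell
identity tables, GMT gene-set files, and two-column cluster label tables.
All readers transparently accept gzip-compressed files.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

LAYER_RAW = "raw_counts"
LAYER_NORMALIZED = "normalized"
LAYER_SCALED = "scaled"


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with barcode and gene-name axes.

    ``values`` may be a dense ndarray or a scipy sparse matrix; rows are
    cells, columns are genes.  ``layer_tag`` records what the values are:
    raw UMI counts, depth-normalized log counts, or per-gene z-scores.
    A scaled matrix keeps a reference to its raw-count parent (``raw``)
    so that dropout (zero raw count) queries remain possible downstream.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    layer_tag: str = LAYER_RAW
    raw: "ExpressionMatrix | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} barcodes for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene names for {n_genes} matrix columns"
            )
        for name, ids in (("barcode", self.cell_ids), ("gene", self.gene_ids)):
            uniq, counts = np.unique(ids.astype(str), return_counts=True)
            if (counts > 1).any():
                dup = uniq[counts > 1][0]
                raise ValueError(f"duplicate {name} {dup!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if len(idx) == 0:
            import difflib

            near = difflib.get_close_matches(
                gene, [str(g) for g in self.gene_ids], n=3
            )
            hint = f"; similar: {', '.join(near)}" if near else ""
            raise KeyError(f"gene {gene!r} not in matrix{hint}")
        return int(idx[0])

    def column(self, gene: str) -> np.ndarray:
        j = self.gene_index(gene)
        col = self.values[:, j]
        if sp.issparse(col):
            col = col.todense()
        return np.asarray(col).ravel()

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        vals = self.values[mask_or_idx]
        raw = self.raw.subset_cells(mask_or_idx) if self.raw is not None else None
        return ExpressionMatrix(
            vals, self.cell_ids[mask_or_idx], self.gene_ids, self.layer_tag, raw
        )


@dataclass
class CellIdentity:
    """Per-cell sgRNA/target assignments for a pooled CRISPR screen.

    ``assignments`` is a tidy frame with columns (cell, sgrna, target); a
    cell appearing in several rows carries several guides (high MOI).
    ``ntc_label`` is the target string marking non-targeting controls.
    """

    assignments: pd.DataFrame
    ntc_label: str = "NTC"

    def __post_init__(self) -> None:
        df = self.assignments
        required = ["cell", "sgrna", "target"]
        if list(df.columns[:3]) != required:
            df = df.iloc[:, :3].set_axis(required, axis=1)
        df = df.astype(str).reset_index(drop=True)
        if df.duplicated(["cell", "sgrna"]).any():
            df = df.drop_duplicates(["cell", "sgrna"]).reset_index(drop=True)
        per_sgrna = df.groupby("sgrna")["target"].nunique()
        bad = per_sgrna[per_sgrna > 1]
        if len(bad):
            raise ValueError(
                f"sgRNA {bad.index[0]!r} is mapped to {bad.iloc[0]} distinct targets"
            )
        self.assignments = df

    def cells(self) -> np.ndarray:
        return self.assignments["cell"].unique()

    def targets(self, include_ntc: bool = False) -> list[str]:
        t = sorted(self.assignments["target"].unique())
        if not include_ntc:
            t = [x for x in t if x != self.ntc_label]
        return t

    def moi(self) -> pd.Series:
        """Number of guide assignments per cell."""
        return self.assignments.groupby("cell").size()

    def cells_for_target(self, target: str) -> np.ndarray:
        df = self.assignments
        return df.loc[df["target"] == target, "cell"].unique()

    def targets_of_cell(self) -> pd.Series:
        return self.assignments.groupby("cell")["target"].apply(
            lambda s: tuple(sorted(set(s)))
        )

    def control_only_cells(self) -> np.ndarray:
        per_cell = self.assignments.groupby("cell")["target"].apply(set)
        mask = per_cell.apply(lambda s: s == {self.ntc_label})
        return per_cell.index[mask].to_numpy()

    def subset_cells(self, keep: Iterable[str]) -> "CellIdentity":
        keep = set(map(str, keep))
        df = self.assignments[self.assignments["cell"].isin(keep)]
        return CellIdentity(df.reset_index(drop=True), self.ntc_label)


class SignatureSet(dict):
    """Mapping of signature name -> ordered list of member gene symbols."""

    def __setitem__(self, key: str, genes: Sequence[str]) -> None:
        genes = list(genes)
        if not genes:
            raise ValueError(f"signature {key!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {key!r} has duplicate genes")
        super().__setitem__(key, genes)


def _open_text(path: Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_sibling(mtx_path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = mtx_path.parent / f"{stem}{suffix}"
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"none of {stems} found next to {mtx_path} (searched with/without .gz)"
    )


def read_expression_matrix(
    path: str | Path,
    format: str = "mtx_triplet",
    genes_in_rows: bool = True,
) -> ExpressionMatrix:
    """Read raw UMI counts from a MatrixMarket triplet dir/file or dense TSV.

    For ``mtx_triplet``, ``path`` is either the ``matrix.mtx[.gz]`` file or
    the directory holding it plus ``features.tsv``/``genes.tsv`` and
    ``barcodes.tsv``; the triplet is stored genes x cells (10x dialect) and
    is transposed on read.  For ``dense_tsv`` the default orientation is
    genes in rows (``genes_in_rows=False`` for cells in rows).
    """
    path = Path(path)
    if format == "mtx_triplet":
        if path.is_dir():
            mtx = _find_sibling(path / "matrix.mtx", ["matrix.mtx"])
        else:
            mtx = path
        feat_path = _find_sibling(mtx, ["features.tsv", "genes.tsv"])
        bc_path = _find_sibling(mtx, ["barcodes.tsv"])
        with _open_text(feat_path) as fh:
            feats = pd.read_csv(fh, sep="\t", header=None, dtype=str)
        # 10x features files carry (id, symbol[, type]); use the symbol
        gene_ids = feats.iloc[:, 1 if feats.shape[1] > 1 else 0].to_numpy()
        with _open_text(bc_path) as fh:
            barcodes = pd.read_csv(fh, sep="\t", header=None, dtype=str).iloc[:, 0].to_numpy()
        with _open_text(mtx) as fh:
            mat = mmread(fh)
        mat = sp.csr_matrix(mat)
        if mat.shape != (len(gene_ids), len(barcodes)):
            raise ValueError(
                f"triplet header {mat.shape} does not match "
                f"{len(gene_ids)} features x {len(barcodes)} barcodes"
            )
        return ExpressionMatrix(mat.T.tocsr(), barcodes, gene_ids, LAYER_RAW)
    if format == "dense_tsv":
        with _open_text(path) as fh:
            df = pd.read_csv(fh, sep="\t", index_col=0, comment="#")
        if genes_in_rows:
            df = df.T
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
            LAYER_RAW,
        )
    raise ValueError(f"unknown format {format!r}")


def write_expression_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    format: str = "mtx_triplet",
    genes_in_rows: bool = True,
) -> None:
    """Write counts as a 10x-style triplet directory or a dense TSV."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        mat = sp.coo_matrix(m.values).T  # genes x cells on disk
        mmwrite(str(path / "matrix.mtx"), mat, field="integer"
                if np.issubdtype(np.asarray(mat.data).dtype, np.integer) else "real")
        pd.DataFrame({0: m.gene_ids, 1: m.gene_ids, 2: "Gene Expression"}).to_csv(
            path / "features.tsv", sep="\t", header=False, index=False
        )
        pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", header=False, index=False)
        return
    if format == "dense_tsv":
        df = pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.gene_ids)
        if genes_in_rows:
            df = df.T
        df.to_csv(path, sep="\t")
        return
    raise ValueError(f"unknown format {format!r}")


def read_cell_identity(path: str | Path, ntc_label: str = "NTC") -> CellIdentity:
    """Read a (cell, sgrna, target) table; multi-row cells are high-MOI."""
    with _open_text(Path(path)) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, comment="#")
    lower = [c.lower() for c in df.columns]
    if {"cell", "sgrna", "target"} <= set(lower):
        df = df.rename(columns=dict(zip(df.columns, lower)))
        df = df[["cell", "sgrna", "target"]]
    else:
        df = df.iloc[:, :3].set_axis(["cell", "sgrna", "target"], axis=1)
    return CellIdentity(df, ntc_label=ntc_label)


def write_cell_identity(identity: CellIdentity, path: str | Path) -> None:
    identity.assignments.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> SignatureSet:
    """Read a GMT file: name, description, then tab-separated gene symbols."""
    sigs = SignatureSet()
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, genes = fields[0], fields[2:]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    warnings.warn(
                        f"duplicate gene {g!r} in signature {name!r}; deduplicated"
                    )
                seen[g] = None
            sigs[name] = list(seen)
    return sigs


def read_cluster_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (barcode, cluster) -> Series indexed by barcode."""
    with _open_text(Path(path)) as fh:
        df = pd.read_csv(fh, sep="\t", header=None, dtype=str, comment="#")
    if df.iloc[0, 0].lower() in {"cell", "barcode"}:
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="cluster")
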