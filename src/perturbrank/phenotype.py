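"""Marker and signature phenotyping ("virtual FACS") and network assembly.

A gene's — or a gene set's average — expression stands in for a sorting
marker: cells are scored in silico instead of being physically sorted.
Engine results thresholded on FDR become edges of a target-marker-
phenotype network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def signature_score(
    scaled: ExpressionMatrix, genes: Sequence[str], layer: str = "scaled"
) -> np.ndarray:
    """Per-cell mean expression of the present signature genes.

    Scores are averaged over the scaled layer by default (means of
    z-scores); ``layer="raw"`` averages the attached raw counts instead.
    Absent genes are dropped with a warning; an empty intersection is a
    hard error.
    """
    source = scaled
    if layer == "raw":
        if scaled.raw is None:
            raise ValueError("no raw layer attached to this matrix")
        source = scaled.raw
    elif layer != "scaled":
        raise ValueError(f"unknown layer {layer!r}")
    available = set(map(str, source.gene_ids))
    present = [g for g in genes if str(g) in available]
    missing = [g for g in genes if str(g) not in available]
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from matrix: "
            f"{', '.join(map(str, missing[:5]))}"
        )
    if not present:
        raise ValueError("no signature gene present in the matrix")
    cols = np.column_stack([source.column(g) for g in present])
    return cols.mean(axis=1)


@dataclass
class NetworkEdge:
    """One FDR-passing link between a perturbation target and a marker."""

    target_id: str
    marker_id: str
    phenotype_label: str
    sign: str
    score: float
    fdr: float
    condition: str


def build_network(
    results,
    fdr_cutoff: float,
    phenotype_labels: Mapping[str, str] | None = None,
    condition: str = "",
) -> list[NetworkEdge]:
    """Assemble FDR-thresholded edges from engine results.

    ``results`` is either a list of RRA results (an edge is kept when
    min(fdr_neg, fdr_pos) < cutoff) or a DataFrame with columns
    (target, marker, score, fdr).  Edge sign follows the score sign;
    edges come back sorted by (target, marker) for determinism.
    """
    if not (0 < fdr_cutoff <= 1):
        raise ValueError("fdr_cutoff must lie in (0, 1]")
    phenotype_labels = phenotype_labels or {}
    rows = []
    if isinstance(results, pd.DataFrame):
        for _, r in results.iterrows():
            if r["fdr"] < fdr_cutoff:
                rows.append(
                    (str(r["target"]), str(r["marker"]),
                     float(r["score"]), float(r["fdr"]))
                )
    else:
        for r in results:
            fdr = min(r.fdr_neg, r.fdr_pos)
            if fdr < fdr_cutoff:
                rows.append((r.target_id, r.marker_id, r.score, fdr))
    edges = [
        NetworkEdge(
            target_id=t,
            marker_id=m,
            phenotype_label=phenotype_labels.get(m, m),
            sign="+" if score > 0 else "-",
            score=score,
            fdr=fdr,
            condition=condition,
        )
        for t, m, score, fdr in sorted(rows, key=lambda x: (x[0], x[1]))
    ]
    logger.info("network: %d edges at FDR < %g", len(edges), fdr_cutoff)
    return edges


def edges_table(edges: Iterable[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target": e.target_id,
                "marker": e.marker_id,
                "phenotype": e.phenotype_label,
                "condition": e.condition,
                "sign": e.sign,
                "score": e.score,
                "fdr": e.fdr,
            }
            for e in edges
        ],
        columns=["target", "marker", "phenotype", "condition", "sign",
                 "score", "fdr"],
    )


def write_network(edges: list[NetworkEdge], tsv_path=None, graphml_path=None):
    """Export edges as a flat TSV and/or GraphML for standard viewers."""
    if tsv_path is not None:
        edges_table(edges).to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        import networkx as nx

        g = nx.DiGraph()
        for e in edges:
            g.add_node(e.target_id, kind="target")
            g.add_node(e.marker_id, kind="marker",
                       phenotype=e.phenotype_label)
            g.add_edge(
                e.target_id,
                e.marker_id,
                sign=e.sign,
                score=e.score,
                fdr=e.fdr,
                condition=e.condition,
            )
        nx.write_graphml(g, graphml_path)


def random_marker_panel(
    genes: Sequence[str], k: int = 50, seed: int = 0
) -> list[str]:
    """Uniform sample of k marker genes without replacement.

    Drives the false-positive evaluation workflow: permuted identities
    tested against randomly chosen markers should yield no discoveries.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    genes = np.asarray(genes, dtype=object)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds {len(genes)} available genes")
    rng = np.random.default_rng(seed)
    return list(rng.choice(genes, size=k, replace=False))
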