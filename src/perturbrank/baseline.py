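"""Cluster-enrichment baseline for perturbation detection.

The classical workflow clusters cells on expression and asks whether the
cells carrying a given knockout concentrate in some cluster.  A target is
"enriched" in a cluster when its carriers make up more than ``min_frac``
of the cluster and the 2x2 chi-squared association test survives BH
adjustment.  Perturbations that shift only one or a few genes rarely move
whole-transcriptome clustering, which is exactly the insensitivity the
rank-aggregation engine is designed to overcome.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io import CellIdentity
from .significance import benjamini_hochberg

logger = logging.getLogger(__name__)


def cluster_enrichment(
    labels: pd.Series,
    identity: CellIdentity,
    min_frac: float = 0.20,
    fdr_cutoff: float = 0.25,
    yates: bool = False,
) -> pd.DataFrame:
    """Chi-squared enrichment of target carriers within each cluster.

    For every (target, cluster) pair a 2x2 table (in/out of cluster x
    carrying/not carrying target) is tested without continuity correction
    (``yates=True`` enables it); p-values are BH-adjusted across all
    pairs.  ``frac`` is carriers-in-cluster / cluster size; a pair is
    enriched iff frac > min_frac and adjusted p < fdr_cutoff.  Degenerate
    margins are skipped with p = 1.
    """
    labels = labels.astype(str)
    id_cells = set(map(str, identity.cells()))
    common = [c for c in labels.index if str(c) in id_cells]
    if not common:
        raise ValueError("no overlap between labeled cells and identity cells")
    labels = labels.loc[common]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for an enrichment test")
    total = len(labels)
    carrier_sets = {
        t: set(map(str, identity.cells_for_target(t))) & set(map(str, common))
        for t in identity.targets(include_ntc=False)
    }
    rows = []
    for target, carriers in carrier_sets.items():
        n_car = len(carriers)
        for cl in clusters:
            in_cluster = set(map(str, labels.index[labels == cl]))
            a = len(carriers & in_cluster)
            b = len(in_cluster) - a
            c = n_car - a
            d = total - a - b - c
            table = np.array([[a, b], [c, d]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                p = 1.0
                logger.info("degenerate margin for (%s, %s); p set to 1",
                            target, cl)
            else:
                _, p, _, _ = chi2_contingency(table, correction=yates)
            frac = a / len(in_cluster) if in_cluster else 0.0
            rows.append((target, cl, frac, p))
    out = pd.DataFrame(rows, columns=["target", "cluster", "frac", "chi2_p"])
    out["adj_p"] = benjamini_hochberg(out["chi2_p"].to_numpy())
    out["enriched"] = (out["frac"] > min_frac) & (out["adj_p"] < fdr_cutoff)
    return out
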