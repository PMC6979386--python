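import numpy as np
import pytest

import perturbrank as pr


def prepare(raw):
    """Drop empty cells and scale, keeping the raw layer attached."""
    totals = raw.dense().sum(axis=1)
    kept = raw.subset_cells(totals > 0)
    return pr.normalize_and_scale(kept)


@pytest.fixture(scope="session")
def effect_screen():
    """Small screen where every target down-regulates its own gene."""
    targets = [f"G{i + 1:04d}" for i in range(10)]
    cfg = pr.SimConfig(
        n_cells=400,
        n_genes=40,
        n_targets=10,
        seed=11,
        effects=pr.own_gene_effects(targets, 0.3),
    )
    raw, identity, truth = pr.simulate_screen(cfg)
    return cfg, raw, identity, truth


@pytest.fixture(scope="session")
def null_screen():
    """Screen with no implanted effects: every p-value family is null."""
    cfg = pr.SimConfig(n_cells=300, n_genes=30, n_targets=8, seed=23)
    raw, identity, truth = pr.simulate_screen(cfg)
    return cfg, raw, identity, truth


@pytest.fixture
def tiny_matrix():
    counts = np.array([[5, 0], [0, 0], [0, 1]])
    return pr.ExpressionMatrix(
        counts, ["c1", "c2", "c3"], ["g1", "g2"], "raw_counts"
    )
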