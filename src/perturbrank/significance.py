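"""Shared permutation machinery and multiple-testing procedures.

Both statistical engines assess significance the same way: the sgRNA
assignment labels are shuffled against the cells (each cell's guide bundle
travels intact, so per-target cell counts and per-cell MOI are preserved),
the statistic is recomputed, and an add-one empirical p-value is formed.
Benjamini-Hochberg controls the FDR across each test family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import CellIdentity


@dataclass(frozen=True)
class PermutationPlan:
    """Reproducible schedule of label permutations.

    The permutation for round ``r`` depends only on ``(seed, r)``, so
    engines sharing a plan see byte-identical shuffles.
    """

    n_perm: int
    seed: int
    scheme: str = "shuffle_labels"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.scheme != "shuffle_labels":
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")

    @property
    def floor(self) -> float:
        """Smallest attainable empirical p-value, 1/(n_perm+1)."""
        return 1.0 / (self.n_perm + 1)

    def permutation(self, n: int, round: int) -> np.ndarray:
        """Permutation array of 0..n-1 for the given round."""
        if round >= self.n_perm:
            raise ValueError(f"round {round} >= n_perm {self.n_perm}")
        rng = np.random.default_rng((self.seed, round))
        return rng.permutation(n)


def permute_identity(
    identity: CellIdentity, plan: PermutationPlan, round: int
) -> CellIdentity:
    """Reassign guide bundles to cells according to one permutation round.

    Cell barcodes are permuted against their assignment bundles: each
    cell's set of guides stays together, so the multiset of per-cell MOIs
    and every target's cell count are invariant.
    """
    cells = np.sort(identity.cells().astype(str))
    perm = plan.permutation(len(cells), round)
    mapping = dict(zip(cells, cells[perm]))
    df = identity.assignments.copy()
    df["cell"] = df["cell"].map(mapping)
    return CellIdentity(df, identity.ntc_label)


def empirical_pvalue(observed: float, permuted, tail: str = "le") -> float:
    """Add-one permutation p-value: (1 + #qualifying) / (1 + B).

    ``tail`` selects which permuted values count as at least as extreme:
    ``le`` (permuted <= observed), ``ge``, or ``two_sided_abs`` on
    absolute values.
    """
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("permuted values must be non-empty")
    if tail == "le":
        count = int((permuted <= observed).sum())
    elif tail == "ge":
        count = int((permuted >= observed).sum())
    elif tail == "two_sided_abs":
        count = int((np.abs(permuted) >= abs(observed)).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + count) / (1 + permuted.size)


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
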