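"""Synthetic single-cell CRISPR screens with known ground truth.

The generator emulates the statistical features the engines must cope
with: negative-binomial UMI counts with an extra dropout layer, zero-
truncated Poisson multiplicity of infection, Bernoulli knockout efficacy,
non-targeting control cells, and multiplicative perturbation effects on
chosen genes.  Everything is byte-reproducible from a single seed, and
the emitted files use the exact formats the readers consume, so the
fixtures double as format tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import poisson

from .io import CellIdentity, ExpressionMatrix, write_cell_identity, write_expression_matrix
from .preprocess import normalize_and_scale


@dataclass
class SimConfig:
    """Screen-generation parameters.

    ``nb_dispersion`` is the negative-binomial size parameter r
    (var = mu + mu^2/r; r -> inf recovers Poisson).  ``depth_mean`` sets
    the expected total UMI count per cell, split across genes by a
    long-tailed baseline unless ``gene_means`` overrides it.  Dropout
    adds zeros with probability expit(-slope * log(mu)), so lowly
    expressed genes drop out more often; slope 0 disables the layer.
    ``effects`` lists (target, gene, multiplier) perturbation effects
    applied to the mean when the per-(cell, target) efficacy Bernoulli
    succeeds.  ``assignment_plan`` optionally fixes each cell's target
    tuple explicitly (empty tuple = control cell), overriding the MOI
    model — used to build deliberately confounded designs.
    """

    n_cells: int = 1000
    n_genes: int = 100
    n_targets: int = 20
    moi_mean: float = 1.0
    nb_dispersion: float = 2.0
    depth_mean: float = 2000.0
    dropout_logit_slope: float = 1.0
    effects: tuple = ()
    knockout_efficiency: float = 1.0
    ntc_frac: float = 0.1
    seed: int = 0
    gene_means: np.ndarray | None = None
    depth_sigma: float = 0.25
    sgrnas_per_target: int = 2
    ntc_label: str = "NTC"
    assignment_plan: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_targets > self.n_genes:
            raise ValueError(
                "n_targets exceeds n_genes: own-gene effects would be "
                "unresolvable"
            )
        if not (0 <= self.knockout_efficiency <= 1):
            raise ValueError("knockout_efficiency must lie in [0, 1]")
        if not (0 <= self.ntc_frac <= 1):
            raise ValueError("ntc_frac must lie in [0, 1]")
        for t, g, mult in self.effects:
            if mult < 0:
                raise ValueError(f"multiplier for ({t}, {g}) must be >= 0")

    def gene_names(self) -> np.ndarray:
        return np.array([f"G{i + 1:04d}" for i in range(self.n_genes)],
                        dtype=object)

    def target_names(self) -> np.ndarray:
        """Targets knock out the first ``n_targets`` genes (same ids)."""
        return self.gene_names()[: self.n_targets]


@dataclass
class SimTruth:
    """Ground truth of a simulated screen.

    ``effects`` is the configured (target, gene, multiplier) table;
    ``applied`` records which (cell, target) knockouts actually took
    effect after the efficacy draws.
    """

    effects: pd.DataFrame
    applied: pd.DataFrame

    def write(self, path) -> None:
        self.effects.to_csv(path, sep="\t", index=False)


def own_gene_effects(targets, multiplier: float) -> tuple:
    """Each target down/up-regulates only its own gene."""
    return tuple((t, t, multiplier) for t in targets)


def _zero_truncated_poisson(rng, lam: float, size: int) -> np.ndarray:
    if lam <= 0:
        return np.ones(size, dtype=int)
    u = rng.uniform(np.exp(-lam), 1.0, size=size)
    return poisson.ppf(u, lam).astype(int)


def simulate_screen(cfg: SimConfig):
    """Generate (raw counts, cell identity, ground truth) for one screen.

    Per cell: a control flag (probability ``ntc_frac``) or a
    zero-truncated Poisson MOI with targets sampled without replacement;
    per carried target a Bernoulli efficacy draw; gene means are baseline
    x depth factor x the product of applicable effect multipliers; counts
    are negative binomial with an extra dropout layer.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_names()
    targets = cfg.target_names()
    t_index = {t: i for i, t in enumerate(targets)}
    cells = np.array([f"cell{i + 1:05d}" for i in range(cfg.n_cells)],
                     dtype=object)

    if cfg.gene_means is not None:
        base = np.asarray(cfg.gene_means, dtype=float)
        if base.shape != (cfg.n_genes,):
            raise ValueError("gene_means must have length n_genes")
    else:
        base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
        base = base / base.sum() * cfg.depth_mean

    # cell -> tuple of carried targets (empty = control-only cell)
    if cfg.assignment_plan is not None:
        if len(cfg.assignment_plan) != cfg.n_cells:
            raise ValueError("assignment_plan length must equal n_cells")
        carried = [tuple(ts) for ts in cfg.assignment_plan]
    else:
        is_ntc = rng.random(cfg.n_cells) < cfg.ntc_frac
        mois = _zero_truncated_poisson(rng, cfg.moi_mean, cfg.n_cells)
        carried = []
        for i in range(cfg.n_cells):
            if is_ntc[i]:
                carried.append(())
            else:
                k = min(int(mois[i]), cfg.n_targets)
                picked = rng.choice(cfg.n_targets, size=k, replace=False)
                carried.append(tuple(targets[j] for j in np.sort(picked)))

    # efficacy draws decide which carried knockouts actually take effect
    applied_rows = []
    applied_mask = np.zeros((cfg.n_cells, cfg.n_targets), dtype=bool)
    for i, ts in enumerate(carried):
        for t in ts:
            if rng.random() < cfg.knockout_efficiency:
                applied_mask[i, t_index[t]] = True
                applied_rows.append((cells[i], t))

    mult = np.ones((cfg.n_cells, cfg.n_genes))
    gene_pos = {g: j for j, g in enumerate(genes)}
    for t, g, m in cfg.effects:
        if t not in t_index:
            raise ValueError(f"effect references unknown target {t!r}")
        if g not in gene_pos:
            raise ValueError(f"effect references unknown gene {g!r}")
        rows = applied_mask[:, t_index[t]]
        mult[rows, gene_pos[g]] *= m

    depth = rng.lognormal(mean=0.0, sigma=cfg.depth_sigma, size=cfg.n_cells)
    mu = base[None, :] * depth[:, None] * mult

    r = cfg.nb_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(mu > 0, r / (r + mu), 1.0)
    counts = rng.negative_binomial(r, p)
    counts[mu == 0] = 0

    if cfg.dropout_logit_slope > 0:
        with np.errstate(divide="ignore"):
            logmu = np.where(mu > 0, np.log(mu), 0.0)
        p_drop = np.where(mu > 0,
                          expit(-cfg.dropout_logit_slope * logmu), 0.0)
        counts[rng.random(mu.shape) < p_drop] = 0

    raw = ExpressionMatrix(counts.astype(np.int64), cells, genes, "raw_counts")

    rows = []
    for i, ts in enumerate(carried):
        if not ts:
            k = rng.integers(cfg.sgrnas_per_target)
            rows.append((cells[i], f"sg_{cfg.ntc_label}_{k + 1}",
                         cfg.ntc_label))
        else:
            for t in ts:
                k = rng.integers(cfg.sgrnas_per_target)
                rows.append((cells[i], f"sg_{t}_{k + 1}", t))
    identity = CellIdentity(
        pd.DataFrame(rows, columns=["cell", "sgrna", "target"]),
        ntc_label=cfg.ntc_label,
    )
    truth = SimTruth(
        effects=pd.DataFrame(list(cfg.effects),
                             columns=["target", "gene", "multiplier"]),
        applied=pd.DataFrame(applied_rows, columns=["cell", "target"]),
    )
    return raw, identity, truth


def write_screen(raw, identity, truth, outdir) -> None:
    """Emit the triplet matrix, identity TSV, and truth TSV into a dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(raw, outdir, format="mtx_triplet")
    write_cell_identity(identity, outdir / "identity.tsv")
    truth.write(outdir / "truth.tsv")


def _prepare(raw):
    """Drop empty cells and scale; QC thresholds are meant for real data."""
    totals = raw.dense().sum(axis=1)
    kept = raw.subset_cells(totals > 0)
    return normalize_and_scale(kept)


def power_sweep(
    base_cfg: SimConfig,
    axis: str,
    levels,
    n_reps: int = 10,
    engine: str = "rra",
    n_perm: int = 300,
    seed: int = 0,
    detect_fdr: float = 0.05,
    effect_multiplier: float = 0.3,
) -> pd.DataFrame:
    """Detection power across a swept design axis.

    ``axis`` is ``target_expression`` (baseline mean of each target's own
    gene), ``moi`` (mean guides per cell at fixed total cells), or
    ``cells_per_target``.  Each replicate simulates a screen whose
    targets down-regulate their own genes by ``effect_multiplier``, runs
    the chosen engine, and reports the fraction of targets detected
    (own-gene negative effect at FDR < ``detect_fdr``) plus the fraction
    whose own gene ranks in the top 10 of the target's transcriptome scan
    (a regression-engine readout, reported whenever the regression runs).
    """
    from .lr import build_design_matrix, lr_test
    from .rra import rra_test

    levels = list(levels)
    if any(b > a for a, b in zip(levels, levels[1:])) and any(
        b < a for a, b in zip(levels, levels[1:])
    ):
        raise ValueError("levels must be monotone")
    master = np.random.default_rng(seed)
    if not base_cfg.effects:
        base_cfg = replace(
            base_cfg,
            effects=own_gene_effects(base_cfg.target_names(),
                                     effect_multiplier),
        )
    records = []
    for level in levels:
        for rep in range(n_reps):
            sub_seed = int(master.integers(2**31 - 1))
            cfg = replace(base_cfg, seed=sub_seed)
            if axis == "target_expression":
                means = np.full(cfg.n_genes,
                                cfg.depth_mean / cfg.n_genes)
                means[: cfg.n_targets] = level
                cfg = replace(cfg, gene_means=means)
            elif axis == "moi":
                cfg = replace(cfg, moi_mean=float(level))
            elif axis == "cells_per_target":
                cfg = replace(cfg, n_cells=int(level * cfg.n_targets))
            else:
                raise ValueError(f"unknown sweep axis {axis!r}")
            raw, identity, _ = simulate_screen(cfg)
            scaled = _prepare(raw)
            targets = [t for t in cfg.target_names()]
            detected = []
            top10 = []
            if engine == "rra":
                for t in targets:
                    res = rra_test(scaled, scaled.raw, t, identity,
                                   n_perm=n_perm, seed=sub_seed)
                    mine = next(r for r in res if r.target_id == t)
                    detected.append(mine.fdr_neg < detect_fdr
                                    and mine.score < 0)
            elif engine == "lr":
                D = build_design_matrix(identity, scaled.cell_ids)
                sm = lr_test(D, scaled, n_perm=n_perm, seed=sub_seed)
                gene_pos = {g: j for j, g in enumerate(sm.gene_ids)}
                for t in targets:
                    i = sm.target_ids.index(t)
                    j = gene_pos[t]
                    detected.append(sm.fdrs[i, j] < detect_fdr
                                    and sm.scores[i, j] < 0)
                    order = np.lexsort((-np.abs(sm.scores[i]), sm.pvals[i]))
                    top10.append(int(np.where(order == j)[0][0]) < 10)
            else:
                raise ValueError(f"unknown engine {engine!r}")
            records.append(
                {
                    "level": level,
                    "rep": rep,
                    "fraction_detected": float(np.mean(detected)),
                    "fraction_top10": float(np.mean(top10)) if top10
                    else float("nan"),
                }
            )
    return pd.DataFrame(records)
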