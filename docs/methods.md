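# Methods

## The model

A pooled single-cell CRISPR screen yields, per cell, a UMI count vector
over genes and a set of detected sgRNAs, each mapping to one target gene
or element. `perturbrank` treats the guide→cell assignment as the
experimental label and the expression matrix as the readout, and asks two
questions at different granularities.

### Rank aggregation (one marker, all targets)

Cells are ranked by the marker's scaled expression. For a target carried
by `n` of the `M` ranked cells, the rank percentiles `u_i = r_i/M` are
sorted; under the null hypothesis of exchangeable guide assignment the
k-th smallest percentile follows Beta(k, n+1−k), equivalently the
binomial tail P(Binom(n, u) ≥ k). The enrichment statistic ρ is the
minimum order-statistic p-value, truncated to respect dropout:

- positive selection uses the descending ranking and keeps only the
  first `j` order statistics, where `j` counts target cells with nonzero
  raw marker counts — a zero count cannot witness *high* expression;
- negative selection uses the ascending ranking, where the zero-count
  block occupies the front of the list; the target's `j` zero-count
  cells are excluded and ρ is the minimum over positions `j+1..n`.
  A zero count is ambiguous between true silencing and capture dropout,
  so it is treated as non-evidence in both directions.

Degenerate truncations (`j = 0` positive, `j = n` negative) set ρ = 1.
ρ itself is not a calibrated p-value (it is a minimum over dependent
order statistics), so significance comes from permutations: guide
bundles are reassigned to random cells (per-target cell counts and
per-cell MOI are preserved), ρ is recomputed, and
`p = (1 + #{ρ_perm ≤ ρ_obs}) / (1 + B)`. The add-one estimator bounds p
below by 1/(B+1) and avoids zero p-values. BH adjustment runs across
targets within one marker and direction. The two directions combine into
a signed selection score `s = log p_neg` if `p_neg < p_pos`, else
`−log p_pos` (natural log; 0 on ties), so negative scores mean the
perturbation lowers the marker.

Ties in the ranking (including the zero block) are broken by barcode
lexicographic order — deterministic and seed-independent; ranks inside
the zero block are excluded from ρ in the direction where they matter.
The nonzero fraction α of the marker is computed and reported on the
ranking, but the truncation actually applied is the per-target `j`.

### Ridge regression (all targets, all genes)

With scaled expression `Y` (M × N) and binary design `D` (M × K),
`S = (DᵀD + λI)⁻¹ DᵀY`, solved by Cholesky factorization of the K × K
system (never an explicit inverse; jitter 1e-10 only if factorization
fails; λ = 0 is allowed only for nonsingular designs, and the error
names collinear columns). λ defaults to 0.01 — small enough to leave
well-identified effects essentially unshrunk, large enough to regularize
co-occurring targets. Non-targeting controls enter as an explicit NTC
design column by default (keeps the closed form unchanged); an
alternative mode centers each gene on the control-only cells
(`center_by_ntc`). Permutations shuffle the correspondence between
expression rows and identity rows with one global permutation per round,
preserving within-cell MOI correlation; since DᵀD is invariant under row
permutation, the factorization is computed once. Per-entry p-values are
two-sided on |s| by default (one-sided available); BH runs per target
row across genes for transcriptome scans, and per marker column across
targets for phenotype scans (`query_marker`).

## Preprocessing

Cells with fewer than 500 expressed genes or more than 10% mitochondrial
reads are removed (strict inequalities: boundary cells are retained;
mitochondrial genes are identified by configurable name prefix, default
`MT-`/`mt-`). Remaining cells are depth-normalized to 10⁴ counts, log1p
transformed, regressed on per-cell technical covariates, and per-gene
z-scored (sample sd; zero-variance genes map to zero columns). Every
step is toggleable.

The covariate regression (log total UMI, plus mitochondrial fraction
when mito genes are present) is not cosmetic. Shallow cells carry extra
dropout zeros in *every* gene, which creates a shared depth component
across genes; without removing it, a randomly labeled cell set that
happens to be shallow looks coherently "negatively selected" on many
markers at once. Rank-based statistics are invariant to per-cell
monotone transforms applied uniformly, but not to this per-cell offset.
The regression removes the linear part of the effect; the discrete
zero-pattern itself cannot be regressed away, which is the main residual
source of dependence between tests run on the same screen (see
Limitations).

## Phenotypes, networks, baseline

A signature score is the per-cell mean of the scaled expression of the
present member genes (raw-layer averaging available); as an RRA marker,
a signature's dropout flag is set only when every member gene has zero
raw count. FDR-thresholded engine results become edges of a
target–marker–phenotype network (sign from the score; deterministic
order; TSV + GraphML export). The cluster-enrichment baseline tests each
(target, cluster) 2×2 table with Pearson's chi-squared (no continuity
correction by default, the Yates flag exists), BH-adjusts across all
pairs, and calls a pair enriched when target carriers exceed 20% of the
cluster at adjusted p < 0.25; "fraction" is carriers-in-cluster over
cluster size.

## The simulator

Per cell: a control flag (probability `ntc_frac`) or a zero-truncated
Poisson MOI with targets drawn without replacement; per carried target a
Bernoulli(`knockout_efficiency`) draw decides whether its effects apply.
Gene means are a long-tailed lognormal baseline summing to `depth_mean`
(default 2000 UMIs/cell; overridable per gene), times a per-cell
lognormal depth factor (σ = 0.25), times the product of applicable
multiplicative effects. Counts are negative binomial with size
`nb_dispersion` (default 2; size → ∞ recovers Poisson), with an extra
dropout layer that zeroes a count with probability
`expit(−slope·log μ)` (slope default 1, so a mean-1 gene drops out half
the time and a mean-50 gene ~2% — this layer exercises the dropout
truncation independently of NB sampling zeros; slope 0 disables it).
Knockout efficacy acts on the mean, not by post-hoc count editing.
Everything derives from one seed; emitted files use exactly the formats
the readers consume.

What the simulator does **not** model: transcriptome correlation
structure (pathways, cell cycle), batch effects, doublets, or guide
detection errors. Passing tests therefore demonstrate the statistical
machinery under clean NB-with-dropout conditions, not robustness to
every artifact of real screens.

## Study conditions used in tests and the acceptance script

Problem sizes were fixed from power arithmetic before measuring: the
empirical p-value floor 1/(B+1) must allow BH-adjusted significance for
the family size in play (e.g. detecting one target among 10 at FDR 0.05
needs B ≥ 200; a row family of 100 genes needs B ≥ 2000).

- Exact oracles: beta order statistics vs binomial tails on a 0.1
  percentile grid up to n = 5; ridge vs dense normal-equations solves on
  50 random systems (M ≤ 50, K ≤ 10, N ≤ 20); permutation p-values vs
  exhaustive enumeration on screens small enough to enumerate (M ≤ 8,
  n ≤ 3, B = 10⁴).
- Null calibration: 200 cells, 20 targets, 50 random markers, shuffled
  labels, B = 200, both engines, 10 screens.
- Recovery: 0.3× own-gene knockdown, ~100 cells/target, B = 1000,
  20 screens.
- Expression dependence: target baseline means {0.5, 2, 8, 32} at fixed
  0.3× knockdown, 10 replicates per level, B = 300.
- MOI contrast: 240 cells, 30 targets, 120 genes at uniform mean 3 (so
  dropout bites and the low-MOI arm is genuinely underpowered, matching
  the regime where low-MOI screens rank only half their targets on top),
  MOI 1 vs 4 on paired seeds, regression engine, top-10 transcriptome
  rank per target.
- Deconvolution: two targets co-occurring in 80% of perturbed cells with
  opposite-direction effects (0.2× down vs 4× up), B = 2000; the
  regression separates them, rank aggregation attributes the first
  target's effect to both.
- Baseline contrast: 20 targets each knocking down only its own gene
  (~30 cells/target); k-means labels (k = 6) feed the cluster-enrichment
  baseline while RRA scans each target's own gene.

`power_sweep` reports the top-10 fraction via the regression engine
regardless of the detection engine: the metric is a per-target
transcriptome scan, which is the regression use case; a per-gene RRA
scan would be quadratic in the gene count and measures nothing extra.

## Numerical choices

- Order-statistic p-values use the regularized incomplete beta function;
  inputs are validated sorted in [0, 1].
- Permutations for round r are generated by a fresh RNG seeded with
  (seed, r), so engines sharing a plan see identical shuffles and
  results are byte-reproducible and chunk-size independent.
- The permutation comparison uses ≤ (ties count as extreme) — the
  conservative choice.
- BH is the standard step-up procedure (delegated to statsmodels).
- Scaling uses the sample sd (ddof = 1); single-cell matrices skip the
  z-score (no variance to estimate).

## Limitations

- Tests of different (target, marker) pairs on one screen share the
  ranking and the cell set, so run-level discovery counts are bursty
  even though each p-value is marginally exact: one coincidentally
  extreme cell set can clear the FDR threshold on several correlated
  markers at once. Covariate regression shrinks but does not eliminate
  this; treat small per-run discovery counts on permuted labels as the
  expected cost of dependence, not as miscalibration.
- Rank aggregation pools all cells of a target's guides and cannot
  attribute effects among co-occurring targets; that is the regression
  engine's job, and the high-MOI conflation is demonstrated, not hidden.
- The ridge model has no covariate columns (batch, cell cycle) and no
  sparsity; effects are estimated jointly but linearly.
- Guide-level heterogeneity (different efficiencies per sgRNA of one
  target) is simulated only through the per-(cell, target) efficacy
  Bernoulli, not modeled in the estimators.
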