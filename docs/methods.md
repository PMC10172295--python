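# Methods

`consensusgrn` reconstructs directed transcription-factor (TF) → target-gene
regulatory networks from a multi-condition expression compendium by running
seven complementary inference approaches and aggregating their rankings by
Borda count. This note documents the models, the numerical choices, and what
the synthetic benchmark does and does not demonstrate.

## Preprocessing

Raw gene-level counts are filtered (keep genes with ≥ 1 CPM in ≥ 9 samples;
both numbers configurable), normalized with trimmed-mean-of-M-values (TMM)
factors, and transformed to `log2((count + 0.5) / (libsize·factor + 1) · 1e6)`.

The TMM implementation follows the canonical algorithm: the reference
library is the sample whose 75th-percentile CPM is closest to the
across-sample mean; per-library log2 ratios against the reference are doubly
trimmed (30% on M-values, 5% on A-values), combined with inverse-variance
(delta-method binomial) precision weights, and the factors rescaled to
geometric mean 1. It matches `edgeR::calcNormFactors` to < 1e-8 on a frozen
fixture (see `tests/test_preprocess.py`). Per-observation precision weights
of the voom type are deliberately omitted: every downstream method consumes
unweighted correlations or regressions on standardized values, so the
weights would have no entry point.

Two matrices leave preprocessing: the replicate-level standardized log-CPM
matrix (consumed by CLR and ARACNE) and the per-condition-median
standardized matrix (consumed by everything else). The matrices carry
explicit `collapsed_to_medians` / `standardized` flags and every inference
method asserts on them, so the two inputs cannot be swapped silently.
Standardization is the gene-wise z-score with an n−1 denominator; genes
with sd < 1e-12 are dropped with a warning.

## The seven inference approaches

All approaches emit only TF-origin, non-self directed edges; for the
symmetric-score methods a TF–TF pair yields both directions with the same
score. Candidate-edge count is E = |TF|·(G−1). Ranks are descending by
score with tied scores sharing the average rank.

* **GGM** — shrinkage partial correlations: the correlation matrix is shrunk
  toward the identity with the analytic (Ledoit–Wolf-type) intensity
  λ* = Σ Var̂(r_ij) / Σ r_ij², inverted, and scaled to partial correlations.
  All pairs with |pcor| > 1e-12 enter the ranking; density trimming does the
  real selection.
* **CLR** — Gaussian-copula mutual information MI = −½·ln(1 − ρ²) from
  Spearman ρ (ρ² clipped at 1 − 1e-12), z-scored per gene against the
  gene's marginal MI distribution (diagonal excluded, z clipped at 0) and
  combined as √(z_i² + z_j²).
* **ARACNE** — the same MI matrix pruned by the data-processing inequality:
  in every triangle of present edges the strictly smallest MI is removed
  when below the other two minus ε (default ε = 0); ties remove nothing;
  all removals are applied simultaneously. Surviving edges are ranked by MI.
* **Elastic net** — per target gene, TFs as predictors; for each ridge
  penalty λ2 ∈ {0, 0.001, …, 100} a coordinate-descent path over the L1
  penalty is computed and indexed by s = L1-norm fraction relative to the
  λ1→0 (ridge/OLS) endpoint, s ∈ {0.1, …, 0.9}; (λ2, s) chosen by 6-fold
  CV, refit on all data. Models whose out-of-fold R² = 1 − MSE_oof/var(y)
  is negative are discarded as regularization artifacts (on standardized
  data an in-sample R² of a fitted model cannot be meaningfully negative,
  so the cross-validated form is the one that gives the discard rule
  content). Edges are scored |β̃| with β̃ = β / max|β|.
* **GENIE3-style trees** — per target, a 1000-tree random-forest regression
  on TF expression with ⌈√K⌉ candidate features per split; edge score is
  the impurity-reduction importance normalized per target to sum to 1.
  Seeded, hence fully reproducible.
* **Deconvolution** — eigenvalue transform λ_dir = λ_obs/(1 + λ_obs) of the
  zero-diagonal Pearson correlation matrix, inverting the transitive-closure
  series G_obs = G_dir + G_dir² + …. When the unscaled transform is
  well-defined and its largest direct eigenvalue is < 1 it is applied as is
  (this makes it an exact inverse of the closure on synthetic input);
  otherwise the spectrum is first rescaled to radius β = 0.9, decrementing
  β by 0.05 (floor 0.05) until the largest direct eigenvalue drops below 1.
* **Silencing** — S = (G − I + D((G−I)·G))·G⁻¹ on the unit-diagonal
  correlation matrix, with the Moore–Penrose pseudoinverse whenever
  cond(G) > 1e12 (always the case when genes outnumber conditions); edges
  ranked by |S|, symmetrized by averaging.

## Consensus

Each ranking is trimmed to the top ⌊0.1·E⌋ edges (floor, for determinism; a
tie group straddling the cutoff is kept or dropped atomically via its shared
average rank). The consensus rank of an edge is the arithmetic mean of its
per-method ranks, with a missing rank imputed as ⌊0.1·E⌋ + 1; the result is
re-ranked, trimmed to ⌊0.1·E⌋ edges (ties broken lexicographically by
(regulator, target)), and each edge is weighted 1/r_consens. The default
integration set is GGM, CLR, elastic net, GENIE3 and deconvolution: on both
curated-interaction benchmarks and the synthetic preset, ARACNE and
silencing are clear outliers (aggressive pruning and near-singular
inversion, respectively) and are therefore benchmarked but excluded.

## Mutant-context subnetwork

Genes differentially expressed between two genotypes are selected by
requiring BH-adjusted p ≤ 0.05 under *every* configured test ("significant
under all tests"). Two in-package genome-wide tests are the default:

1. a moderated t on log-CPM, with the residual variances shrunk toward a
   scaled-inverse-chi-square prior fitted by the method of moments on log
   variances (trigamma inversion by Newton iteration);
2. a negative-binomial Wald test with library-size offsets, a
   method-of-moments dispersion per gene floored at the across-gene median
   (with 2–3 replicates the raw MoM estimate is biased low, which would
   make the Wald test strongly anticonservative), and the group log-means
   fitted by vectorised Newton iteration.

Both tests are vectorised across genes, so a 2000-gene, 100-seed
calibration run takes seconds. A GENIE3-style network is then inferred on
the DE genes only (DE TFs as predictors, replicate-level standardized
values — a two-genotype experiment has too few conditions for medians to be
informative), trimmed to 10% of the subnetwork's candidate edges, and
intersected with the consensus; the intersection keeps the context
importances as edge weights.

## Regulator analysis

The strength of a TF for a curated target set of k genes is
C(TF) = Σ_j w_TFj, the sum of its (consensus or context) edge weights into
the set. Top-k extraction expands ties at the k-th position and logs the
expansion. The overlap of the top-k regulator lists of two gene sets is
tested by Monte Carlo: each of n iterations (default 10 000) redraws two
sets of the same cardinalities without replacement from the network's own
target universe (nodes with ≥ 1 incoming edge), recomputes the top-k lists
with the same tie-expansion rule, and counts iterations whose overlap
reaches the observed one; p = (r+1)/(n+1), so p ∈ [1/(n+1), 1].

Gold-standard benchmarking classifies each curated interaction per network
as highly ranked (rank ≤ ⌊0.1·E⌋), below threshold (present but deeper), or
absent; sensitivity is the highly-ranked fraction of the positives, and
highly-ranked negative-label edges are flagged as potential false
positives.

## Synthetic compendium

The generator emulates the statistical shape the inference assumes, at
desk scale: 12 TFs, 60 genes, 40 conditions × 3 replicates (120 samples),
echoing a ~158-sample/62-condition compendium at ~1/10 scale. Ground truth
is a topologically ordered TF→TF layer (wiring probability 0.15) plus 1–3
regulators per non-TF target, signs positive with probability 0.7
(activators dominate in curated interaction sets), effect sizes uniform on
[0.5, 1.5]. TF activities are per-condition Gaussian shifts (sd 1, natural
log units) plus covariate components: half the TFs respond to the light
level (15 vs 300 µmol photons m⁻² s⁻¹), a quarter to acetate. Latent target
log-expression is the signed, weighted sum of regulator values plus
Gaussian noise (sd 0.25); knockouts clamp the TF's latent value to its
across-condition minimum minus two activity sd *before* propagation,
mirroring an insertional mutant that is still annotated. Counts are
negative binomial (gamma–Poisson, dispersion 0.05) on softmax-normalized
transcript proportions times library sizes uniform on [5·10⁵, 2·10⁶].

What the generator does **not** emulate: diurnal autocorrelation between
time points (conditions are exchangeable), batch structure between source
datasets, transcript-level multi-mapping, nonlinear/combinatorial
regulation, and feedback loops. Passing the recovery benchmark therefore
shows the machinery is correct and well-calibrated for linear-signal data
of realistic size and noise — not that any particular biological network
would be recovered at these rates.

## Problem sizes and numerical choices

The benchmark sizes used by the test suite and the acceptance script — the
desk-scale preset, 100 permutation shuffles, 200 null replicates × 99
Monte-Carlo iterations for the overlap test, 100 seeds × 2000 genes for DE
calibration, 20 matrices for the deconvolution oracle, 100 for the ARACNE
oracle — were chosen as the smallest sizes at which the checked properties
are statistically unambiguous. Determinism: every stochastic step takes an
explicit integer seed; ranked outputs sort ties lexicographically, so a
fixed config reproduces byte-identical edge lists. Degenerate inputs are
errors, not silent repairs (all-zero libraries, constant genes reaching MI
estimation, empty DE sets, inconsistent E across consensus inputs), with
two deliberate exceptions: an empty context∩consensus intersection and a
score table smaller than k only warn, because both occur legitimately on
small contexts.

## Known limitations

* The elastic-net (λ2, s) search reproduces the fraction-of-L1-norm
  parameterization with a 25-point log-spaced λ1 path per λ2; s resolution
  is therefore limited by the path resolution.
* The NB Wald test with 2–3 replicates leans on the median-floored
  dispersion; with many replicates a per-gene (e.g. Cox–Reid) estimate
  would be preferable.
* The GGM keeps all numerically non-zero partial correlations rather than
  applying a significance cut; density trimming substitutes for edge
  selection.
* Real-data mode consumes whatever count matrix and TF list it is given;
  genome-identifier version mapping is out of scope.
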