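# Methods

This note documents the statistical models, numerical choices and synthetic
data behind `soyblup`, and what its tests do and do not establish.

## Dosage coding and marker QC

Genotype calls (HapMap-style tables with single-character IUPAC codes, `N`
missing) are converted to major-allele dosages x ∈ {0, 1, 2}. The major
allele at a marker is the more frequent allele among non-missing calls,
with heterozygotes contributing one copy of each allele; frequency ties at
0.5 resolve to the lexicographically smaller base so the coding is
deterministic. Heterozygous calls score dosage 1 regardless of phase — the
intended material is inbred lines (F4- and F5-derived), where residual
heterozygosity is rare but legal.

Per-marker QC uses two statistics: PMV (fraction of lines with a missing
call) and MAF (frequency of the rarer allele among non-missing calls,
min(θ, 1−θ) with θ the major-allele frequency). Filtering is sequential:
PMV first with an inclusive threshold (keep PMV ≤ cutoff), then MAF with a
strict one (keep MAF > cutoff; exact equality excluded, implemented with a
1e-9 guard against float noise). The full evaluation grid crosses 27 PMV
levels (1–20% by 1, then 25, 30, 40, 50, 60, 70, 80) with 12 MAF levels
(0.05–0.10 by 0.01, then 0.15–0.40 by 0.05) and 3 imputation methods — 972
marker datasets. The third method slot, `external`, ingests a pre-imputed
matrix (e.g. from a haplotype-library imputer run outside the package);
nothing in the package re-implements haplotype imputation.

## Imputation

*Naive*: missing entries at marker j are replaced by 2θ̂_j (the observed
mean dosage), which leaves per-marker allele frequencies unchanged and
produces a complete real-valued matrix. This is the baseline, not an
information-adding method.

*Random forest*: a missForest-style iterative scheme run chromosome-wise.
Starting from the naive fill, markers are visited in order of ascending
missingness; each marker's observed entries are regressed on all other
markers of the same chromosome with a random-forest regressor and its
missing entries replaced by predictions. Sweeps repeat until the
missForest difference statistic ||new − old||²/||new||² first increases
(the previous sweep's values are then kept) or `max_iter` is reached.
Hyperparameters default to missForest practice: 100 trees, square-root
predictor subsampling, at most 10 sweeps; regression (not classification)
on the dosage scale. Imputed dosages stay continuous in [0, 2] — kernels
accept real dosages, so rounding to {0, 1, 2} would only discard
information. A chromosome with a single marker has no predictors and falls
back to the naive fill with a warning. Runs are reproducible given a seed.

## Relationship kernels

Standardization is VanRaden-style: w_ij = (x_ij − 2θ_j)/√(2θ_j(1−θ_j)),
with θ_j taken from the matrix being standardized unless a reference vector
is supplied (needed to put selection candidates on a training-set scale).
Monomorphic markers are rejected with a pointer to MAF filtering.

* **G** = WW′/p — additive realized relationships. For inbred material the
  mean diagonal sits near 1 + f ≈ 2.
* **G∘G** — elementwise square of G; additive-by-additive covariance under
  the Cockerham–Kempthorne assumptions; PSD by the Schur product theorem.
* **K**_aa = ZZ′/m — pairwise-product epistatic kernel, one column of Z per
  marker pair (w_j ⊙ w_k), m = p(p−1)/2 pairs, evaluated through
  ZZ′ = ½[(WW′)∘(WW′) − (W∘W)(W∘W)′] so the pair matrix is never formed.
  The 1/m normalization keeps diagonal magnitudes comparable to G∘G; any
  alternative constant rescales the kernel and is absorbed by its variance
  component, so model fits and predictions are unaffected.

On multi-family inbred data G∘G and K_aa are strongly collinear (upper-
triangle correlation > 0.9 in the test suite) and neither is orthogonal to
G — which is why two-kernel fits reapportion variance without changing
predictions much.

## Mixed models

One REML engine underlies everything: y = Xb + Σ_k Z_k u_k + e with
independent random blocks. It profiles out the residual variance and
optimizes the restricted likelihood over variance *ratios* γ_k = σ²_k/σ²_e
on the log scale, bounded to [1e-6, 1e6] (components can hit the zero
boundary but never go negative). All linear algebra goes through the
Woodbury identity on M = I + D Z′Z D; for large sparse indicator designs M
is factored by sparse LU with symmetric-mode ordering, otherwise by dense
Cholesky. Multi-ratio searches use Nelder–Mead with moment-based starting
values (for trial models) or multiple restarts (for two-kernel fits).

*BLUEs* (`adjust_phenotypes`): genotype and location fixed,
replicate-within-location and block-within-replicate random. Fixed/random
status is a design choice — augmented designs identify block effects
through the repeated checks, and treating blocks as random recovers
information from incomplete blocks. The reported BLUE is the line effect
plus the mean location effect (grand scale). Saturated designs (one plot
per line, nothing else) return the plot values exactly.

*Trial variance components* (`trial_varcomps`): same data with genotype and
genotype-by-location random; location fixed; replicate and block random
where the design has them. Entry-mean heritability is
H² = σ²_G/(σ²_G + σ²_G×E/e + σ²_ε/(e·r)) with e the number of locations
and r the median replicate count per location. Single-location data flag
the interaction as not estimable (it is inseparable from genotype) and use
σ²_G×E = 0, which reduces the formula to the single-environment form.

*G-BLUP* (`GBLUP` / `GBLUPResults`): y_i = μ + Σ_k g_ik + e_i with
g_k ~ N(0, σ²_k K_k). One kernel: the kernel is eigendecomposed once, the
model rotated to diagonal form, and the profile REML criterion minimized
exactly over log λ = log σ²_g/σ²_e by bounded scalar search (tolerance
1e-8) — no iterative linear solves, and the optimum is checkable against a
brute-force grid (the test suite does). Two kernels: each kernel is
factored through its eigendecomposition (eigenvalues below 1e-10 of the
largest dropped) and the generic engine searches two log ratios with three
Nelder–Mead restarts. BLUPs for all kernel lines, including unphenotyped
selection candidates, come from the conditional expectation
ĝ_all = γ K[all, train] V*⁻¹(y − μ̂) — no refitting. With K = WW′/p this
reproduces ridge-regression (RR-BLUP) marker-effect predictions exactly,
which the suite verifies to 1e-8.

## Evaluation

*Predictive ability* is the correlation between observed phenotypes and
predicted breeding values in held-out data. Cross-validation runs `reps`
independent random k-way partitions; each fold is predicted from the rest
by a fresh G-BLUP fit, and one ability per replicate is computed by pooling
the held-out predictions. Two details matter and are deliberate:

1. The *breeding value* ĝ, not μ̂ + ĝ, enters the correlation. Per-fold
   intercepts are estimated from the complementary folds, so under weak
   signal they anti-correlate with the fold mean and pooling them biases
   the ability by about −1/√(fold size).
2. Each fold's predictions are standardized (zero mean, unit variance)
   before pooling. The REML variance ratio sets a fold-specific prediction
   scale; under weak signal those scales correlate with fold-level chance
   alignment and bias pooled correlations negative. With real signal the
   standardization is numerically inconsequential (differences in the third
   decimal in side-by-side checks), but it makes the null well calibrated.

A caveat the test suite works around explicitly: replicated CV of a single
phenotype draw has an irreducible dataset-level ability offset (standard
deviation ≈ 0.05 at n = 300, independent of marker count and replicate
count), because all replicates share the one realized phenotype vector.
Null calibration is therefore assessed across independent phenotype draws.

The 95% CI on mean ability is a percentile bootstrap (2,000 resamples of
replicate abilities). Accuracy = ability/√H², clipped to [−1, 1] with a
warning. The genomic-vs-phenotypic comparison returns r_A/H_X, the largest
cycle-length ratio at which genomic selection still wins genetic gain per
unit time under the indirect-selection response identity.

The training-population-size sweep fixes a random validation set per
replicate (default 50 lines), grows the training set by nested single-line
increments, and records ability on the fixed set at each (strided) size.
Undefined correlations at tiny sizes are excluded from that size's mean
with a count. Fold assignment and sampling use seeded generators
throughout; identical seeds give bit-identical results.

Desk-scale defaults: tests run 2–25 CV replicates and strided sweeps with
40–200 replicates; the full 200-replicate CV and 1000-replicate sweep of a
production analysis are plain parameter choices (`reps=`, `stride=1`).

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes; its defaults describe a 301-line, 34-family elite soybean
breeding population evaluated for grain yield at 4 locations × 2
replications.

* *Population*: family sizes are drawn from a clipped lognormal (range
  1–28, median ≈ 8) and repaired to sum to 301. Each family crosses two
  founder haplotypes sampled from a shared 30-haplotype base pool (shared
  ancestry across families), then selfs with recombination (Poisson ~1
  crossover per chromosome per meiosis) for 6 generations, leaving
  residual heterozygosity under 2% — F5-derived-like inbreds. (Fewer
  selfing generations leave too much heterozygosity to match that
  material.)
* *Genome*: 20 chromosomes; base-pool haplotypes come from a latent AR(1)
  Gaussian along each chromosome thresholded at Beta(0.35, 0.35) base
  frequencies — distance-decaying LD plus a U-shaped frequency spectrum
  whose minor-allele side gives the heavy rare-allele tail typical of GBS
  SNP sets. Default marker density (150/chromosome) is a desk-scale
  choice; tests that need the law of large numbers use 5,000 markers.
* *Missingness*: per-marker missing probability c₁ + c₂·sin⁸(πt) of the
  relative position t — low near chromosome ends, peaking mid-chromosome
  (pericentromeric), affinely calibrated so the marker-level mean/median
  missingness hits 0.18/0.08. The pre-masking matrix is left intact as
  ground truth for masking experiments.
* *Phenotypes*: breeding values are sums of effects at randomly sampled
  polymorphic QTL (optionally plus pairwise-product epistatic effects),
  rescaled so the realized genetic variance equals the target exactly
  (default 12.9). Plot values add fixed-location effects (sd 3), random
  replicate (sd 1) and incomplete-block (sd 1) effects, line-by-location
  interaction (variance 7.28) and plot residual (variance 31.4) in an
  augmented design: blocks of 27–39 entries, each carrying the same three
  replicated check cultivars. Location/replicate/block effect sizes are
  package choices of plausible magnitude (the trait scale is arbitrary);
  the analysis estimates and removes them, so conclusions do not hinge on
  their exact values. The trait mean defaults to 0 — only variances matter
  downstream.

What the generator does *not* emulate: genotyping error and heterozygote
undercalling, maturity-group confounding with family, selection during
line development, and coalescent-exact LD. Passing tests therefore show
that the pipeline's estimators recover the structure they model — not that
real GBS data meet that model. One consequence worth naming: on complete
error-free genotypes, rare markers carry real QTL signal, so the observed
advantage of high-MAF marker sets for small training populations emerges
only in the realistic setting where rare markers are also mostly missing
and imputation turns them into noise (the two marker recipes compared are
the strict-missingness/MAF > 0.05 and permissive-missingness/MAF > 0.30
sets of the training-size analysis).

## Numerical and degenerate-input conventions

* Variance ratios bounded to [1e-6, 1e6] on the log scale; estimates at
  the lower bound are reported as (numerically) zero components.
* Kernel PSD tolerance: minimum eigenvalue ≥ −1e-8 relative to the largest
  entry; kernels are symmetrized (½(K + K′)) on construction.
* All-missing markers: flagged in QC (PMV 1, MAF undefined), fatal in
  imputation (error naming the marker).
* Constant phenotypes drive σ̂²_g to the boundary and give constant
  predictions; constant fold predictions pool as zeros.
* Grid cells leaving fewer than 50 markers are skipped with a logged
  reason, as are `external` cells with no supplied matrix.
* Saturated fixed designs with random terms raise (no residual degrees of
  freedom) rather than returning arbitrary components.

## Known limitations

* The two-kernel REML search is derivative-free; with strongly collinear
  kernels (G vs G∘G on inbred families) the likelihood is nearly flat in
  one direction and the split between the two genetic components is
  weakly identified — their sum and the predictions are stable.
* `adjust_phenotypes` fits all lines as fixed effects in one pass; designs
  beyond a few thousand lines would want an absorbing formulation.
* Multi-trait models, Bayesian whole-genome regressions, dominance
  kernels and spatial field-trend corrections are out of scope.
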