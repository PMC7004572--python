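# Methods

## Scope and model

`scgrn` reconstructs transcription-factor (TF) → gene regulatory networks
from pooled, transcriptionally barcoded single-cell RNA-seq. The modelling
chain is:

1. **Preprocessing.** The cells × genes UMI count matrix is reduced by
   removing genes with zero variance across cells, then transformed by
   `log2(x + 1)`. No library-size normalization or batch depth equalization
   is applied before inference: per-task scaling inside the regression stage
   absorbs depth differences, and cross-condition depth variation is part of
   the signal the multitask decomposition is designed to handle.
2. **TF activity (TFA) estimation.** Expression is modelled as
   `X = P A` with `X` genes × cells (log2 expression), `P` the genes × TFs
   prior connectivity and `A` the latent TFs × cells activities. The system
   is overdetermined; `A` is the least-squares minimizer of `‖PA − X‖²`,
   computed by minimum-norm least squares so that rank-deficient priors
   (duplicated TF target profiles) cannot fail. A TF with no prior targets
   uses its own expression row as an activity proxy (zeros when the TF gene
   is not measured). Expression is not centered before the solve; activities
   are relative quantities and the regression stage centers per fit.
3. **Single-task regression (BBSR).** Per gene, candidate regulators are the
   ten TFs with the highest CLR score plus every prior regulator (never the
   gene's own TF). Ordinary least squares is fit on centered data to every
   subset of the candidates and the subset minimizing
   `BIC = n·ln(RSS/n) + q·ln(n)` is kept. Ties keep the smaller, then
   lexicographically first subset. The edge score for a chosen regulator is
   its explained-variance fraction `1 − RSS_full / RSS_drop` (OLS refit
   without it), clamped to [0, 1]; optionally scaled by the model's total R²
   (`score_scaled_by_model_r2`, off by default). A Zellner g-prior hook
   exists but applies no bias by default.
4. **Multitask regression (AMuSR).** Condition-defined tasks are fit jointly
   per gene: `W = S + B` with an l1/l∞ penalty (weight `λ_b`) on the
   conserved component `B` and an l1/l1 penalty (weight `λ_s`) on the
   task-specific component `S`. The grid is
   `λ_b = c_b·sqrt(d·ln p / n)` for 20 log-spaced `c_b ∈ [0.1, 10]` and
   `λ_s = c_s·λ_b` for 10 linear `c_s ∈ [1/d + 0.01, 0.99]` (200 pairs, all
   satisfying `1/d < λ_s/λ_b < 1`); the alternative reading
   `λ_b = c_b·d·sqrt(ln p / n)` is available via `lambda_b_formula`.
   The winner is chosen by extended BIC,
   `n·ln(RSS/n) + q·ln n + 2γ·q·ln p` with γ = 1 by default.
5. **Assembly.** Each (bootstrap, task) fit yields a non-negative edge-score
   matrix. Scores are rank combined (average rank on ties, min-max
   normalized to [0, 1]) across bootstraps within a task and then across
   tasks, making confidences invariant to monotone transforms of any input.
   Edges scored zero in every fit are treated as absent. Signs are the sign
   of the mean coefficient across all fits. The global ranked list is cut at
   the longest prefix whose precision against a standard, measured over the
   standard's gene × TF universe, stays ≥ 0.5.
6. **Evaluation.** Precision–recall against a held-out gold standard,
   restricted to its universe, with fitting-prior edges excluded from both
   the list and the positive set. AUPR is the average-precision sum (not
   trapezoidal interpolation); under a uniformly random ranking of the full
   universe its expectation is the universe's positive fraction, which the
   test suite verifies by permutation.

## AMuSR solver

The objective
`Σ_d ‖y_d − A_d(S_{:,d} + B_{:,d})‖² + λ_s Σ|Φ∘S| + λ_b Σ_k max_d |B_{k,d}|`
is minimized by alternating proximal block updates with step `1/L`,
`L = 2·max_d λ_max(A_dᵀA_d)`: soft-thresholding for `S`, a row-wise l∞
proximal step for `B` (via Moreau decomposition against the l1 ball), and —
because the fit term depends on `S + B` only — an exact per-row
repartition of `W` between `S` and `B` that minimizes the penalty at fixed
`W` (the optimal `B` row is `clip(w, ±m)` with the cap `m` found among the
knots of the piecewise-linear penalty cost). Every step is non-increasing in
the objective; the solver records the full objective trace and its largest
observed increase (numerically zero). All 200 grid points are optimized in
lockstep as one vectorized iteration, stopping when every grid point's
relative objective change falls below 1e-2 or after 1000 iterations.
Responses and predictor columns are centered and unit-scaled within each
task before fitting, so one λ grid is meaningful across tasks of different
sequencing depth; coefficients and scores live on the scaled problem.

With a single task the shared component is meaningless (`1/d < λ_s/λ_b < 1`
is unsatisfiable at d = 1): `B` is pinned to zero and the l1 path over `S`
is searched on the 20-point `c_b` scale — a plain lasso path.

Per-task AMuSR edge scores use the same explained-variance definition as
BBSR, but by zeroing the regulator's penalized coefficient in that task's
model rather than refitting the subset by OLS, which would change the model
class.

## Numerical choices

- Mutual information uses 10 equal-width bins per variable over the observed
  range (configurable), in bits; a constant vector has MI 0. CLR z-scores
  within regulator rows and gene columns use population standard deviations,
  negatives clamped to 0, combined as the root sum of squares.
- Best-subset enumeration is exhaustive up to 14 candidates (16384 fits per
  gene); above that, prior regulators are kept and the rest filled by CLR
  rank until the cap. Subset solves are batched per subset size and carry a
  relative ridge of `1e-10·mean(diag(G))` so that collinear bootstrap
  resamples cannot produce singular systems; the chosen subset still matches
  an exact enumeration oracle on every tested instance.
- `RSS = 0` maps to a BIC/EBIC of −∞ (a perfect fit always wins).
- Rank combination with all rank sums equal (e.g. a single constant input)
  returns 0.5 everywhere, keeping the output in [0, 1].
- Bootstrap resample `b` draws from a seed sequence `(seed, b)`, so runs are
  reproducible and individual resamples independent.

## Cross-validation and negative controls

One CV repeat: split the gold standard's genes in half (ceil goes to the
prior side), remove the held-out genes' rows from the fitting prior, run the
pipeline, and score recovery of the held-out half with fitting-prior edges
excluded. Only held-out gold-standard genes are removed from wider priors;
genes never in the gold standard stay. The shuffled-prior control permutes
the prior's rows under fixed gene labels (column sums and edge counts are
preserved exactly). The simulated-data control redraws every cell's gene
counts multinomially from the dataset-wide gene frequency distribution while
keeping each cell's total UMI count and all metadata, so all biological
covariation is destroyed and only sampling noise remains.

Because the assembled network ranks only edges with a nonzero regression
score, its ranked list is a truncated subset of the candidate universe, and
a chance-level truncated list scores *below* the full-universe random
expectation. The negative-control check therefore compares the
shuffled-prior AUPR against the permutation distribution of the same ranked
list in random order; the full-universe expectation (positive fraction) is
verified separately by permutation.

## Synthetic benchmark

The generator emulates a pooled multi-condition experiment. Defaults, chosen
once as the study conditions for the whole test suite:

| parameter | default | rationale |
| --- | --- | --- |
| genes × TFs | 200 × 20 | scaled-down panel keeping genes ≫ TFs |
| targets per TF | 14 | curated yeast gold-standard out-degree (~1403/98) |
| activator fraction | 0.75 | activating interactions dominate curated sets |
| effect magnitudes | U(0.5, 2) log2 units | moderate-to-strong regulation |
| conditions × cells | 3 × 300 | few related tasks, realistic per-task depth |
| condition activity means | N(0, 1) | between-condition regulatory shifts |
| within-condition activity sd | 0.5 | cell-to-cell TF activity fluctuation |
| latent noise sd | 0.25 log2 units | biological/technical residual noise |
| depth | lognormal(σ=0.35) around condition medians ≈ 2250 | rich-media median UMIs/cell; condition-linked depth factors lognormal(σ=0.3) |
| gene base rates | lognormal(σ=1.5), normalized | heavy-tailed transcriptome abundance |

Latent log2 expression is `base + W·activity + noise`; rates are the
per-cell-normalized `2^latent`, and observed counts are a multinomial
downsample at the cell's depth — so counts carry realistic sampling noise
and per-cell totals are exact. TF genes are latent (not in the measured
panel): activity estimation must run through prior targets, which is the
regime the method is built for. Not simulated: cell-cycle structure, doublet
transcript mixing, genotype-specific effects, ambient RNA, and batch
chemistry differences. Passing recovery tests therefore demonstrates that
the estimator chain recovers linear TF→gene structure from multinomially
downsampled counts under condition-driven activity shifts — not that it is
robust to every artifact of real droplet data.

Benchmark truth splits use the same CV machinery as real gold standards:
half of the truth genes become the fitting prior, the other half the
evaluation standard, with disjoint gene sets by construction.

## Problem sizes used by the shipped checks

Parameter recovery runs the default benchmark at 5 bootstraps over 10 seeds
for both BBSR-by-task and AMuSR, comparing true-prior against
shuffled-prior AUPR; the batched subset solves and the lockstep λ-grid
solver keep this tractable on a single CPU. The doublet simulation uses
10⁵ droplets; the null-sampler check 10⁵ UMIs; random-ranking calibration
1000 permutations.

## Known limitations

- The TFA step inherits the conditioning of the prior; strongly correlated
  TF target sets yield correlated activities, and best-subset/lasso stages
  then split credit between them. No network-constrained or non-negative
  activity variants are provided.
- AMuSR fits genes independently; there is no cross-gene shared structure
  beyond the common λ grid.
- Mutual-information preselection uses fixed equal-width binning; very deep
  or very shallow cells shift bin occupancy, which bootstrap averaging only
  partly smooths.
- The precision walk treats the standard's universe as the denominator;
  edges outside the universe ride along above the cutoff but are never
  counted for or against precision.
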