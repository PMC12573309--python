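# Methods

This note documents the statistical model, the estimation algorithm, the
numerical and design choices behind `tosccamm`, and what the synthetic-data
generator does and does not emulate.

## Model

Two long-format views `X` (p features) and `Y` (q features) hold repeated
measurements of the same n individuals on per-individual, possibly disjoint
time grids.  For each component k the observation model is a probabilistic
CCA with a single dynamic latent variable: at time t,

    x_i(t) = f(t; θ_η) w_x,kᵀ + ε_x,i(t),
    y_i(t) = f(t; θ_γ) w_y,kᵀ + ε_y,i(t),

with sparse weight vectors fixed over time and a smooth per-individual latent
trajectory `f`.  The two views' latent variables are two renderings of one
underlying path, which is what licenses predicting one view's scores on the
other view's grid.

### Trajectory families

All families are linear mixed models with a single random intercept per
individual and a fixed time basis:

| family | basis | typical use |
|---|---|---|
| `random_intercept_linear` | (1, t) | drifting processes |
| `random_intercept_polynomial` (degree d) | (1, t, …, t^d) | smooth nonlinear paths; d=3 is the workhorse |
| `change_point` (given s) | (1, t, t², t³, t·1{t>s}) | event-centred series with a post-event slope |
| `passthrough` | — | identity bridge for coinciding grids; reduces the algorithm to plain sparse CCA |

The change point `s` is supplied (default 0, i.e. event-centred time), never
estimated; the post-change term uses `t·1{t>s}` as written, with a
`(t−s)·1{t>s}` variant behind `shift_after_change` since the two
parameterisations differ only in how the jump at `s` is absorbed.  Polynomial
bases are raw powers of the supplied times, with no internal rescaling —
this keeps coefficients directly interpretable on the study's time scale but
can be ill-conditioned for large |t|; centre or scale times upstream if the
grid is wide.

### Mixed-model estimation

Because the only random term is an intercept, the marginal covariance of a
group is `σ_ε²(I + λ11ᵀ)` with `λ = σ_b²/σ_ε²`, and the (restricted)
likelihood profiles analytically down to a smooth scalar function of log λ.
`_lme.py` optimises that profile exactly (bounded scalar minimisation,
`xatol 1e-10`, log λ ∈ [−20, 20]); β̂, σ̂_ε² and the per-individual BLUPs
`λ/(1+λm_i)·(residual sum)` are closed-form given λ.  REML is the default,
ML is available per spec.  A fit costs well under 2 ms, which matters
because trajectory models are refit at *every* NIPALS iteration and inside
every permutation replicate; the solver agrees with `statsmodels.MixedLM` to
~1e−5 on all compared quantities (asserted in the test suite, where MixedLM
serves as the independent reference).  If the scalar optimisation fails the
fit falls back to fixed-effects-only least squares with zero intercept
variance and a `fallback` flag, so an outer loop never aborts mid-iteration.
A boundary solution (λ → 0) is returned as σ_b² = 0 with zero BLUPs.

Prediction for an individual never seen at fit time uses the fixed-effects
curve alone — the BLUP of an unobserved random intercept is its prior mean —
so ids present in only one view are handled without special cases.

## Estimation algorithm

One component, given sparsity levels (p_x, q_y):

1. `η ← X w_x`, normalised to unit Euclidean norm;
2. fit the trajectory of η over X's (id, time) pairs; predict `η̃` on Y's;
3. `w̃_y ← Yᵀ η̃`; top-k soft-threshold to q_y nonzeros; renormalise;
4. `γ ← Y w_y` (unit norm); fit its trajectory; predict `γ̃` on X's rows;
5. `w̃_x ← Xᵀ γ̃`; threshold to p_x; `η ← X w_x` (unit norm);
6. `ρ ← cor(η, γ̃)`; stop when `|ρ(l) − ρ(l−1)| ≤ ξ` (default 1e−6) or after
   `max_iter` (default 100) iterations.

Numerical conventions and their reasons:

- **Thresholding.**  λ = (k+1)-th largest |w̃|; soft-shrink; renormalise.
  Generic inputs keep exactly k nonzeros; boundary ties shrink to exactly
  zero (stable argsort, lower indices first — deterministic).  The operator
  is invariant to positive rescaling of its input, so it commutes with the
  latent-score normalisation.  An all-zero vector is passed through with a
  warning and the component is returned degenerate (ρ = 0, not converged).
- **Weight update.**  The covariance form `Mᵀs` is the default; the full
  least-squares form `(MᵀM)⁻¹Mᵀs` is available via `ls_weights=True`.  With
  standardized columns and unit-norm scores the two differ by column scaling
  only.
- **ρ across mismatched grids.**  η and γ live on different row sets, so the
  correlation is computed between trajectory-aligned quantities: `ρ =
  cor(η, γ̃)` on X's rows, with the Y-side counterpart `cor(γ, η̃)` also
  reported (`rho_y`).
- **Latent normalisation** divides by the Euclidean norm (not the SD): on
  centered data ρ is then a cosine and deflation is an exact projection.
- **Deflation.**  After each component both matrices are deflated by the
  unit-norm latent scores, `M ← M − u(uᵀM)`.  Every column of the deflated
  matrix is orthogonal to u, so latent variables of later components are
  exactly orthogonal to earlier ones.
- **Initialization.**  Random unit vectors from a seeded generator.  By
  default each component runs 5 restarts and keeps the one with the largest
  |ρ|: the thresholded update is greedy, and on simulated data a substantial
  fraction of single random starts converges to a *weaker* component first,
  scrambling the extraction order; restarts make the ordering stable while
  remaining bit-reproducible under the seed.  `n_starts=1` or an explicit
  `init` vector recovers single-start behaviour.
- **Convergence** uses the absolute change in ρ; the raw (signed) change
  would stop on any decrease.

With one visit per individual and `passthrough` trajectories, steps 2 and 4
become identities and the algorithm is exactly the non-longitudinal
thresholded sparse CCA — asserted against an independently coded plain
NIPALS loop at 1e−8 in the tests.

## Model selection

- **Cross-validation** (`cv_select`): folds partition individuals, never
  rows, so all visits of an individual stay together; assignment depends only
  on the seed and the id set.  The out-of-fold criterion is the absolute
  aligned correlation `|cor(X_test w_x, γ̃_test)|`, with the trajectory
  refitted on the held-out individuals as the alignment device (weights come
  from training folds only).  Ties prefer sparser pairs (smaller p_x+q_y,
  then smaller p_x).  Later components are selected on matrices deflated by
  full-data refits of earlier choices.  Folds with fewer than two test
  individuals in either view are skipped with a warning.
- **Adj. CPEV** (`adj_cpev`): fraction of the *original* standardized
  matrix's squared norm captured by the orthogonal projection onto the span
  of the first k latent score vectors (rank-tolerant SVD basis).  Depends on
  the span only, hence invariant to recombination of the scores, and
  nondecreasing in k.
- **Permutation test** (`permutation_test`): the null reassigns whole
  individuals' Y series against X by a seeded permutation of Y's id labels —
  each series stays intact, preserving within-individual correlation, which
  row-level permutation would destroy (inflating type-I error).  Component k
  is refit on the observed fit's deflated matrices for each of B permuted
  datasets; `p_k = (1 + #{|ρ*| ≥ |ρ_k|})/(B+1)`.  Absolute values are used
  on both sides because the sign of a canonical pair is arbitrary under
  weight sign flips.  Sparsity levels during permutation equal the observed
  fit's.  Type-I calibration under an independent-noise null is asserted in
  the test suite (rejection rate within binomial bounds of α).

## Synthetic-data generator

`simulate.generate` emulates a two-component longitudinal study: population
latent curves

    z₁(t) = θ₀t + sin(θ₁t)·t,        z₂(t) = θ₂t + (1 + t/max t)³,

plus a per-individual `N(0, σ_b²)` offset and iid `N(0, σ_ε²)` noise, drive
both views through sparse true weights (equal magnitudes `1/√support`,
alternating signs, disjoint fixed supports across components).  Observation
noise is AR(1) over time within each feature with unit marginal variance
(`ρ_t` on the first off-diagonals), independent across features.  Finally,
exactly `round(miss·n·T)` whole visits are removed uniformly at random per
view — deterministic row counts; an individual may lose none, several or all
visits.

Defaults are the study conditions: n=100, p=10,000, q=200, T=10 visits at
t=1..10, supports 10 (X) and 5 (Y), miss 20%/30%.  Where the study
conditions leave values free we fixed, once: θ₀=0.5, θ₁=0.4, θ₂=−1.2,
σ_b=σ_ε=0.5, ρ_t=0.3.  θ₁ and θ₂ were calibrated at design time so the two
population curves are visibly nonlinear, mutually near-orthogonal over the
grid (|corr| ≈ 0.04) and trackable by the cubic working model (cubic-fit
correlation ≥ 0.99): strongly overlapping or fast-oscillating curves make
the second component unrecoverable *by construction* (deflation removes the
shared part of the paths), which would test the generator rather than the
estimator.  `noise_sd` scales the observation noise (0 = noiseless limit
used by exactness tests).

What the generator does **not** emulate: non-Gaussian or heavy-tailed
features, feature-level (cell-wise) missingness, informative or clustered
visit dropout, cross-feature noise correlation, event-centred time axes, or
weights that drift over time.  Passing tests therefore demonstrate correct
recovery under a well-specified sparse low-rank model with MCAR visit
removal — not robustness to the full messiness of cohort data.

## Problem sizes used in the checks

The full default scale (800×10,000 and 700×200 after missingness) is cheap
for fitting — a K=3 fit takes ~2 s, cross-validation over three grid pairs
~6 s — so generator-fidelity, support-recovery, trajectory-recovery and
nestedness checks all run at full scale.  Permutation testing refits every
component B times; its check runs at p=2,000, q=100, n=60 with B=99, which
is statistically the same setting because the per-refit cost and behaviour
are dominated by rows and the mixed-model fits, not by feature count.  The
type-I calibration uses 50 tiny single-visit replicates (n=20, p=q=4).

## Known limitations

- Only random-intercept longitudinal models are built in: no random slopes,
  splines or ARIMA-type latent dynamics.
- The NIPALS objective is non-convex under the cardinality constraint;
  restarts stabilise but cannot guarantee the global optimum.
- Raw polynomial bases can be badly conditioned on wide or large-valued time
  grids.
- Exactly two views; no per-time-point weights; no inference on individual
  weights (the permutation test addresses component count only).
- The Adj. CPEV uses the span-projection definition; other adjustments for
  non-orthogonal sparse loadings exist and can give different absolute
  levels (ordering is typically unaffected).
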