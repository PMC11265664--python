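# Methods

## Model

`growsaem` fits a nonlinear mixed-effects model specified at the plant
level, with two strata of Gaussian random effects:

```
y_ij  = g(φ_i, t_ij) + ε_ij,      ε_ij ~ iid N(0, σ²),  j = 1..n_i
φ_i   = X_i β + Z_i u + p_i,      p_i  ~ iid N(0, P),   i = 1..N_p
u ~ N(0, K ⊗ G)
```

* `g(φ, t)` is a known growth curve with `m` plant-level parameters.
  Shipped families: logistic `A / (1 + exp(-γ(t − x)))` with fixed scale
  `γ`, asymptotic regression `φ₁(1 − exp(−exp(φ₂) t))`, and a constant
  curve `g(φ, t) = φ₁` that reduces the model to a linear mixed model
  (used by the oracle tests). Any evaluable curve can be registered.
* `X_i` (m×p) and `Z_i` (m×q·N_v) are incidence matrices; `Z_i` is the
  variety-block matrix `(0 … Z_{v_i} … 0)` and is never materialized —
  all algebra uses the per-plant block and the variety index. Designs are
  declared by terms: each term (`"1"` or a covariate name) contributes a
  scaled identity block, so `fixed_terms=["1","x"]` yields
  `X_i = (I_m | x_i I_m)` with β laid out term-major.
* `u` stacks one `q`-vector of genetic effects per variety
  (variety-major). `K` is the variety-by-variety genomic relationship
  matrix; `G` (q×q) the genetic covariance of the effects; `P` (m×m) the
  plant-effect covariance. `K ⊗ G` quantities are always computed through
  factorized identities (`|K ⊗ G| = |K|^q |G|^{N_v}`;
  `u'(K⁻¹ ⊗ G⁻¹)u = tr(G⁻¹ S(u))` with `S(u) = Σ_{v,w} [K⁻¹]_{vw} u_v u_w'`);
  the only dense (q·N_v)² matrix ever formed is the precision of `u | φ`,
  whose size is unavoidable for the exact Gaussian draw.

Assumptions worth making explicit: homoscedastic residuals on the analysis
scale (log-transform heteroscedastic data first — the reader supports
`transform: log`), a common curve family for all plants, covariates
constant within plant, and additive genetic effects through `K`.

## Parameter estimation (SAEM, algorithm A)

Given `(φ, u)` the complete-data likelihood is an exponential family in
θ = (β, σ², P, G), so the stochastic approximation runs on sufficient
statistics rather than on the Q function:

* `rss = Σ_ij (y_ij − g(φ_i, t_ij))²` → `σ² = rss / Σ n_i`;
* per covariate pattern `c` (plants sharing the same `X_i`): sums `S1_c`
  and cross-products `S2_c` of `r_i = φ_i − Z_i u` → `(β, P)` solve the
  coupled GLS system `β = (Σ_c n_c X_c'P⁻¹X_c)⁻¹ Σ_c X_c'P⁻¹S1_c`,
  `P = N_p⁻¹ Σ_c [S2_c − centering]`, iterated to relative change < 1e−8
  (max 50 inner iterations, warning + last iterate on non-convergence);
* the genetic scatter `S(u)` → `G = S(u)/N_v`.

Each SAEM iteration:

1. **Simulation.** `mh_inner = 5` Metropolis transitions per plant on
   `φ_i` targeting `p(φ_i | u, y_i; θ)` (plants are conditionally
   independent given `u`, so all chains advance vectorized), then an
   exact draw of `u | φ` via the Cholesky factor of its precision
   `Σ_i Z_i'P⁻¹Z_i + K⁻¹ ⊗ G⁻¹`.
2. **Stochastic approximation** of the statistics,
   `s ← s + γ_k (s_new − s)`, with `γ_k = 1` for `k ≤ n_burn` and
   `γ_k = (k − n_burn)^(−a)` after; `a = 2/3` by default, constrained to
   (1/2, 1] so that Σγ_k = ∞ and Σγ_k² < ∞.
3. **M-step** by the closed forms above.

Two implementation choices matter at small sample sizes and deserve their
rationale:

**Conditional-expectation statistics.** The `u`-dependent statistics enter
the SA as their exact conditional expectations given `(y, φ)` rather than
as single-draw values: `p(u | φ)` is Gaussian and every statistic is
quadratic in `u`, so `E[S(u) | φ] = M'K⁻¹M + Σ_{v,w}[K⁻¹]_{vw} Cov(u_v, u_w)`
(and analogously for the `r_i` statistics) is available in closed form
from the same factorization used for sampling. With single-draw statistics
and `γ_k = 1`, the G update is replaced wholesale each burn-in iteration by
`S(u)/N_v`, whose relative fluctuation is about `√(2/N_v)` per diagonal; at
a few dozen varieties a run of small draws shrinks G enough that the prior
dominates `u | φ`, and the iteration spirals into the absorbing state
G = 0 (we observed exactly this on the reduced prediction design). The
conditional-expectation form is the standard variance-reduced (exact
partial E-step) SAEM estimator; its covariance term keeps `E[S(u)|φ]` of
order G while the mean term pulls it toward the data-supported value, so
G = 0 becomes repelling. `u` is still drawn every iteration to advance the
Gibbs chain.

**Proposal geometry.** The random walk on `φ_i` is componentwise in the
Cholesky basis of the current `P` (coordinate `j` moves along the `j`-th
Cholesky column, with a dimensionless relative scale), not axis-aligned.
On small samples the M-step can drive `P` to a nearly singular matrix
(perfectly correlated plant effects); the prior quadratic form is then a
razor-thin ridge on which an axis-aligned walk rejects ~90% of arbitrarily
small moves, freezing the chain — and with it the SA statistics, making
the degenerate `P` self-sustaining. Proposals shaped by `P` keep mixing on
and across the ridge. Relative scales start at 1, are tuned by
Robbins–Monro on the log scale (rate `min(0.5, 2/√k)`) toward a target
acceptance of 0.35 during burn-in, and are frozen afterwards so the SAEM
convergence conditions hold in the refining phase.

Other numerical choices: symmetric matrices are symmetrized as
`(M + M')/2`; Cholesky failures retry once with jitter `1e−8·tr(M)/dim`,
then raise; M-step outputs have their eigenvalues floored at a relative
1e−8 so downstream solves stay well-posed when a variance component
degenerates; `σ²` is floored at 1e−12 with a warning (noiseless data).
Initialization: per-plant nonlinear least squares (curve-specific moment
heuristics as starting values and as fallback), β by least squares of the
initial φ on the fixed design, P from the residual covariance, G as a
q×q identity at P's scale with P's leading block copied in, σ² from the
pooled per-plant residuals, u = 0. Divergence (non-finite θ) raises with
the iteration index. The default schedule is 1500 iterations with 1300
burn-in; the package's own studies use 600/500, which the convergence
trajectories show is ample at the sizes involved (trajectory tables are
returned by every fit for inspection).

## Genetic-effect prediction (SAEM, algorithm B)

With θ fixed at θ̂, `û = argmax_u p(u | y; θ̂)` is computed by a second
SAEM run in which φ is the latent variable: MH transitions on φ given the
current u, stochastic approximation of the averaged φ̄, then the
closed-form update

```
u = (Σ_i Z_i'P⁻¹Z_i + K⁻¹ ⊗ G⁻¹)⁻¹ Σ_i Z_i'P⁻¹(φ̄_i − X_i β).
```

The update includes the Gaussian prior term `log p(u; K ⊗ G)`; without it
the maximizer would be the profile estimate, not the posterior mode (on
linear-Gaussian submodels the update then provably recovers the exact
posterior mode, which the tests verify). Because θ is fixed the system
matrix is constant and factorized once. Default schedule: 1000 iterations,
800 burn-in.

## Prediction and cross-validation

Predictions set the plant effect to its prior mean zero:
`φ̂_i = X_i β̂ + Z_i û`, `ŷ_i(t) = g(φ̂_i, t)`. For varieties absent from
the fit, effects come from the Gaussian conditional expectation
`û_new = (K_no K_oo⁻¹ ⊗ I_q) û_obs` (G cancels in the mean; the solve
falls back to a jittered system only if the observed block is singular).

The CV harness builds exact partitions of the scenario's unit set:

* **cv0** — leave one level of the environment covariate out, round-robin
  over levels. At least three distinct levels are required: with two, the
  single level left in training confounds the covariate effect with the
  intercept, so the scheme is reported as infeasible (this check is
  deliberate — a binary treatment covariate cannot support cv0).
* **cv1** — varieties are randomly partitioned into folds; validation
  varieties never contribute observations to training, and their effects
  come from the kinship extension above.
* **cv2** — variety × environment combinations are partitioned; a fold
  that would strip some variety of all training data is re-randomized
  (with a logged notice), and an unsatisfiable configuration raises.

`run_cv` refits θ and û on every training fold (seeds derived
deterministically from the plan seed) and returns signed relative
differences `(pred − ref)/ref` on two scales: observation-scale (predicted
trajectory vs the held-out measurements at their observed times) and,
for simulated data with ground truth, parameter-scale (φ̂ vs the
generating φ). The two scales behave very differently early in growth:
where true heights are near zero relative to the noise standard deviation,
observation-scale relative differences are unbounded (their denominators
are noise), which is why summaries report distributions per time point and
why the package's own accuracy criterion for the prediction study is
stated on the parameter scale. A 90/10 single-split protocol is available
via `folds=10, folds_to_run=1`; the k-fold × repetitions protocol via the
plan parameters.

## Variance analysis

Heritability is reported as the diagonal ratio `G_gg / (G_gg + P_pp)` with
an explicit (g, p) index mapping. When G and P have equal dimensions the
identity mapping applies; in the irrigation-interaction model (G 4×4,
P 2×2) each interaction effect is paired with its trait's P diagonal —
the only coherent pairing since P has no interaction entry. With `G = kP`
every ratio is exactly `k/(k+1)`. Genetic correlations convert Ĝ to a
correlation matrix; marginal correlations average the per-variety marginal
covariance `K_vv · Z_block G Z_block' + P` over varieties under a chosen
covariate setting before converting. The two can differ in sign; both are
reported without interpretation.

## Simulator

`simulate` draws from the model exactly: `u = L_K Ẑ L_G'` (Kronecker
covariance by construction), `p_i` and `ε_ij` i.i.d. Gaussian. Kinship is
simulated as markers-then-GRM rather than as an arbitrary PD matrix, to
preserve GRM-like spectra: per-marker allele frequencies uniform on
[0.05, 0.5], Hardy–Weinberg genotypes coded −1/0/1 for independent
varieties, VanRaden method-1 GRM (markers centered by their empirical
mean, denominator `2Σ p̂_l(1−p̂_l)`), rescaled to unit mean diagonal, with
a 1e−6 diagonal jitter. Sample-centering pins the off-diagonal mean at
`−1/(N_v−1)`; with many markers individual off-diagonals concentrate
there.

Shipped presets:

| preset | plants | varieties | sampling | θ |
|---|---|---|---|---|
| scenario1 (/_100v) | 2000 | 50 / 100 | 45 unit-spaced on [1,45] | μ_A=50, μ_x=13, σ²=4, P=diag(6,0.4), G=diag(25,1.5) |
| scenario2 (/_rich) | 800 | 200 | 10 / 45 regular on [1,45] | same |
| prediction (/_k2) | 1350 | 225 | 10 regular on [1,150] | μ_A=50, μ_B=25, δ_A=0, δ_B=25, σ²=8, P=diag(3,0.1), G=kP, k∈{1,2}; x∈{1,2,3}, 2 plants per level |

Design choices where the design was genuinely open:

* the logistic scale is fixed at γ = 0.3 — with half-time 13 this yields
  near-complete growth over [1, 45];
* the prediction design's observation window is [1, 150]: its half-times
  `μ_B + x δ_B` reach 100, and a window that ends long before the curves
  bend over leaves the asymptote unidentified — empirically the fixed
  effects then drift along the `A·e^{−γx}` ridge with exploding P while
  only σ² remains estimable. Ten regularly spaced points covering the
  curves keep the design sparse and the parameters identified;
* δ_A defaults to 0 (no average environment effect on the asymptote);
  override `theta` to change it;
* plants are allocated evenly across varieties, remainder round-robin;
* P and G defaults are diagonal; off-diagonals can be set via `theta`
  overrides.

Every preset field is overridable, which is how the package's own studies
run at desk scale.

What the simulator does **not** emulate — and hence what passing tests do
not establish about field data: spatial layout and neighbour competition,
measurement-time heteroscedasticity (real height series typically need a
log transform first), missing observations and imputation error,
population structure or pedigree relatedness beyond an unrelated-panel
GRM, curve-family misspecification, and time axes in heat units.

## Problem sizes used by the tests and the reproduction script

The package's own studies run the stated designs at reduced scale, chosen
as the smallest sizes at which the estimators' sampling noise stays well
inside the documented recovery bands: sparse-sampling recovery uses 5
replicates of 50 varieties × 200 plants (600/500 iterations); the
prediction-design studies use 40 varieties × 6 plants (600/500 for
recovery, 400/320 for the CV fits); the linear-submodel equivalence uses
50 plants of 10 varieties against an exact marginal-likelihood optimizer.
`scripts/acceptance.py` re-runs the first and second of these from scratch
and writes the replicate-mean estimates.

## Known limitations

* Standard errors for θ̂ are not computed (no Fisher-information
  machinery); replicate simulations are the intended way to assess
  estimator spread.
* Heritability here is a diagonal-ratio proxy, not a formal quantity; it
  ignores covariate-induced variance and off-diagonal structure.
* The MH kernel adapts only during burn-in; a fit whose θ moves far after
  burn-in (pathologically short burn-in) can end with mis-tuned proposal
  scales — inspect the returned acceptance log.
* `K` must be positive semi-definite up to a small tolerance; rank
  deficiency from duplicated varieties is handled by jitter, but heavy
  rank deficiency will slow the u-draw and can amplify numerical error.
* Observation-scale relative differences are undefined where the true
  signal is zero; rely on the parameter-scale summaries in that regime.
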