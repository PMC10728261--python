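# Methods

## Measurement model

A two-condition task yields single-trial response times
Y_ijkl (person i, task j, condition k, trial l), modeled as

    Y_ijkl ~ Normal(α_ij + x_k θ_ij, σ²),

where x_k is 0 for congruent and 1 for incongruent trials, α_ij is the
person's baseline (true congruent speed), θ_ij the person's true effect,
and σ the within person-by-condition trial-noise SD. The person-level
sample effect d_ij = mean(incongruent) − mean(congruent) is then
distributed N(θ_ij, σ²(1/L₀ + 1/L₁)); with balanced L trials per
condition, d_ij ~ N(μ_θ, σ_θ² + 2σ²/L) marginally. Everything downstream
— attenuation, reliability, the Spearman correction, the hierarchical
models — follows from this decomposition.

All quantities are in milliseconds internally. Readers convert
seconds-valued files on ingest; mixing the two scales silently is the
classic failure mode this rules out.

### One-task model

Random effects θ_i ~ Normal(μ_θ, σ_θ²). Priors (ms scale):

| parameter | prior | why |
|---|---|---|
| α_i | Normal(800, 1000²) | baselines ~800 ms ± 2000 ms; essentially flat |
| σ² | Inverse-Gamma(0.1, 10⁵) | IG(0.1, 0.1) on the seconds² scale; broad |
| μ_θ | Normal(50, 100²) | inhibition effects live in the 10–100 ms range |
| σ_θ² | Inverse-Gamma(2, 30²) | the informative choice; controls shrinkage |

The σ_θ² scale of 30² ms² encodes that true effects cannot vary wildly
across people when mean effects are a few tens of ms (a dominance
argument: if nobody's true effect is negative and the mean is ~60 ms,
the SD cannot much exceed ~25 ms).

### Multi-task model

θ_i ~ N_J(μ, Σ_θ) with Normal(50, 100²) on each μ_j and an
inverse-Wishart prior on Σ_θ with df = J + 3 and scale 1800·I ms².
These hyperparameters are derived, not tuned: the implied marginal on
each diagonal of an IW(ν, S) is Inverse-Gamma((ν−J+1)/2, S_jj/2), so
df = J+3 and S_jj = 1800 reproduce exactly the one-task
Inverse-Gamma(2, 900) prior on each task's σ_θ². Latent correlations are
read off each Σ_θ draw as ρ_jk = Σ_jk/√(Σ_jj Σ_kk).

σ² is shared across tasks by default, matching the generative model used
in the simulation studies; real batteries whose tasks differ in noise
(100–400 ms is common) can be handled by fitting tasks separately with
the one-task model, since a per-task σ_j² multi-task variant is not
implemented.

## Gibbs sampler

All full conditionals are conjugate: normal for each α_ij, each θ_i
(scalar in the one-task model, J-variate in the multi-task model), and
μ; inverse-gamma for σ² and σ_θ²; inverse-Wishart for Σ_θ. The
likelihood enters only through per-cell sufficient statistics (trial
counts, cell means, pooled within-cell sum of squares), so an iteration
costs O(I·J) independent of trial count; a full two-task fit at I = 200,
L = 100 takes well under a second per thousand iterations. For balanced
designs the θ-update's precision matrix is shared across persons and
factored once per iteration.

Chains initialize at method-of-moments estimates (cell means, observed
effects, pooled within-cell variance, the effect covariance plus a small
ridge). Defaults: 2 chains × 5000 iterations, 1000 burn-in, no thinning;
the simulation studies use documented shortened chains (2000 iterations,
500 burn-in) after checking that split-chain R-hat stays below 1.05
there. Seeding is hierarchical (`numpy` SeedSequence spawning), so fits
and whole studies are bit-reproducible from one master seed. Convergence
diagnostics (rank-normalized split R-hat and ESS via arviz) are computed
for group-level parameters; R-hat > 1.05 warns but does not fail, since
a flagged fit is still a fit.

Correctness is established in the test suite by (a) pinning α and σ² on
a tiny instance and matching the Gibbs marginal of σ_θ² against a dense
2-D grid integration of the exact posterior (sup-CDF distance < 0.02),
and (b) fitting zero rows of data, in which case the conditionals reduce
to the priors and the draws must reproduce them (Kolmogorov–Smirnov
against the stated Inverse-Gamma/Normal marginals).

## Classical estimators

*Effects and correlations.* Sample effects per person×task; Pearson
correlations with pairwise person deletion; zero-variance and n < 3
cases flagged as undefined rather than guessed.

*Split-half reliability.* Effects computed on even- vs odd-indexed
trials within each person-by-condition cell (0-based, file order — a
deterministic split), correlated across persons, stepped up with
Spearman–Brown 2r/(1+r).

*Full (variance-components) reliability.* Pooled within-cell trial
variance σ̂² gives each person's effect-error variance
σ̂²(1/L₀ + 1/L₁); subtracting its mean from the observed effect variance
yields a moment estimate of true variance, and the reliability is the
ratio of that estimate to the observed variance. It uses cross-trial
variability like an ANOVA decomposition, is expectation-matched to the
model-implied reliability L·σ_θ²/(L·σ_θ² + 2σ²), and may legitimately be
negative in low-signal data; negative values are reported as-is.

*Spearman correction.* r′ = r_xy/√(r_xx r_yy), deliberately not
truncated; `clip_correlation` is a separate, explicit step. Non-positive
reliability products make the correction undefined and are propagated as
missing (with counts) rather than fabricated.

*Attenuation math.* The signal-to-noise ratio is defined as
γ = σ_θ/σ (not its square root): this is the definition under which the
attenuation factor L/(L + 2/γ²), the worked value .44 at (L=100, γ=1/8),
and ratio columns like σ̂_θ/σ̂ = 15/100 → 0.15 are all mutually
consistent. `required_trials` returns the smallest integer L with
σ√(2/L) ≤ target SE, i.e. ceil(2σ²/SE²).

## Synthetic data

Generators draw baselines α_ij ~ Normal(800, 100²) ms (effects are
invariant to baselines; these values only make the trial tables look
like real RT data), true effects from N_J(μ, Σ_θ), and trials from the
measurement model. Default study conditions mirror a large inhibition
battery: I = 200 persons, L = 100 trials per condition, σ = 200 ms,
σ_θ = 25 ms, task means μ_j = 50 ms. The six-task generator uses a
one-factor truth Σ = w w′ + η²I with loadings
w = (1.5, 5.7, 9.9, 14.1, 18.3, 22.5) ms and η = 10 ms, giving per-task
effect SDs from ~10 to ~25 ms and true correlations from ~0.07 to ~0.80.

What the generator does *not* emulate: skewed RT distributions
(ex-Gaussian/lognormal shapes), sequential and practice/fatigue effects,
per-task noise differences, accuracy, and real-world cleaning artifacts.
Passing tests therefore demonstrate estimator behavior under the ideal
Gaussian measurement model — the regime where the Spearman correction's
assumptions hold exactly — and say nothing about robustness to
distributional misspecification. Simulated RTs are real-valued and can
in principle go negative under 200 ms noise; they are kept for model
fidelity.

## Simulation studies

Three designs: a two-task study over ρ ∈ {.2, .5, .8}, a six-task
one-factor study, and a Spearman-instability study at fixed ρ = .8. Per
replicate the engine records the sample correlation, the
Spearman-corrected value (raw and clipped to [−1, 1]) using
variance-components reliabilities (split-half switchable), and the
multi-task model's posterior mean with a 95% equal-tailed credible
interval. Summaries — RMSE per method (pooled over pairs and
replicates), coverage per ρ level, the fraction of corrected values
above 1 — are always recomputed from the per-replicate records.
Undefined corrections are excluded from RMSE with their count reported.
The instability study defaults to 1000 replicates, enough to pin the
exceedance fraction to about ±1 percentage point.

Problem sizes in the test suite are the package's scaled defaults: 30
replicates at ρ = .2 plus 15 each at .5/.8 for the two-task model study,
15 replicates for the six-task model study, 50 for the six-task
classical study, 1000 for the instability study, with 2 × 2000-iteration
chains for all model fits. Credible intervals are equal-tailed
percentiles (not HPD) — the standard reading of "95% credible interval".

## Numerical notes and limitations

- Within-cell sums of squares are computed as Σy² − (Σy)²/n and floored
  at 0 against float cancellation (safe at RT magnitudes in float64).
- Correlation draws get their diagonal pinned to exactly 1 after the
  Σ_jk/√(Σ_jj Σ_kk) division.
- Σ_θ draws are strictly positive-definite by the inverse-Wishart, so a
  task with essentially no true variability appears as a small diagonal
  entry (with strong shrinkage of its person effects and wide correlation
  intervals), never as a point mass at zero.
- Persons missing a condition cell (or a whole task) are dropped with a
  warning; there is no missing-data augmentation.
- The multi-task model stops at the covariance Σ_θ: no latent-variable
  (factor) decomposition is fitted, and accuracy/diffusion-style joint
  models are out of scope.
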