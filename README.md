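# trialnoise

Trial noise and the recovery of individual-difference correlations in
contrast-based cognitive tasks.

## The problem

Individual-differences research with inhibition tasks (Stroop, flanker,
Simon, ...) scores each person by a condition contrast,
d_i = mean RT(incongruent) − mean RT(congruent), and then correlates
these effects across tasks. Each trial, however, carries noise with a
standard deviation σ that is typically around eight times larger than
the standard deviation σ_θ of people's *true* effects. With L trials per
person per condition, the expected correlation of sample effects is the
latent correlation ρ shrunk by the attenuation factor

    ρ*/ρ = L σ_θ² / (L σ_θ² + 2 σ²) = L / (L + 2/γ²),   γ = σ_θ / σ,

which at typical values (L = 100, γ = 1/8) is 0.44 — observed
correlations are less than half the true ones. The classical remedy,
Spearman's correction r′ = r_xy / √(r_xx · r_yy), is unbiased-ish but
unstable: corrected values routinely exceed 1. The model-based remedy is
a trial-level hierarchical model

    Y_ijkl ~ Normal(α_ij + x_k θ_ij, σ²),    θ_i ~ N_J(μ, Σ_θ),

with an inverse-Wishart prior on the between-task effect covariance Σ_θ,
whose posterior correlations are disattenuated and come with honest
uncertainty. This package implements the whole toolchain for psychologists
and methodologists planning or analyzing such batteries: trial-table I/O
and cleaning, the classical estimators, the closed-form attenuation and
design-planning math, fast conjugate Gibbs samplers for the one-task and
multi-task hierarchical models, trial-level simulators with recorded
ground truth, and a simulation-study engine that scores all three
estimation routes by RMSE and credible-interval coverage.

## Worked example

Simulate a typical two-task battery (200 people, 100 trials per
condition, σ = 200 ms, σ_θ = 25 ms) whose true latent correlation is .8,
then estimate that correlation three ways:

```python
import trialnoise as tn

table, truth = tn.simulate_two_task(rho=0.8, I=200, L=100, rng=42)
eff = tn.person_task_effects(table)
print(eff.summary.round(2).to_string(index=False))

r = tn.sample_correlation(eff, "task1", "task2")
rel = {t: tn.full_reliability(table, t).value for t in ("task1", "task2")}
print(f"sample correlation:    {r:.3f}")
print(f"expected (attenuated): {tn.expected_observed_correlation(0.8, 100, 200, 25):.3f}")
print(f"Spearman-corrected:    {tn.spearman_correction(r, rel['task1'], rel['task2']):.3f}")

model = tn.MultiTaskModel(iterations=2000, burn_in=500, chains=2, seed=1,
                          keep_person_draws=False).fit(table)
print(model.correlation_summary_.round(3).to_string(index=False))
```

prints

```
 task  mean_effect  sd_effect  n_persons
task1        49.45      35.73        200
task2        49.02      39.69        200
sample correlation:    0.342
expected (attenuated): 0.351
Spearman-corrected:    0.803
task_a task_b  mean    lo    hi
 task1  task2 0.663 0.467 0.818
```

Reading the output: people's sample effects have SD ≈ 36–40 ms even
though true effects have SD 25 ms — the excess is trial noise
(√(25² + 2·200²/100) ≈ 37.7 ms). The sample correlation, 0.34, sits at
the closed-form attenuated value 0.8 × 0.44 ≈ 0.35. Spearman's
correction happens to land near the truth here (0.80), but across
replicates it scatters widely and ~10% of corrected values exceed 1.
The hierarchical model's posterior mean (0.66) is disattenuated relative
to the sample value, and its 95% credible interval [0.47, 0.82] says,
honestly, that the correlation is not well localized even with 80,000
trials.

The same estimators are exposed on the command line:

```bash
trialnoise plan --sigma 200 --sigma-theta 25 --n-trials 100 --target-se 10
trialnoise simulate two-task --rho 0.8 --seed 1 -o trials.csv
trialnoise fit-multi trials.csv --iterations 2000 --seed 1
trialnoise study six-task --replicates 10 -o results/
```

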