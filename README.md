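# popdisorg

Analysis toolkit for quantifying the **progressive disorganization of
visually guided behavior and neuronal population activity** across a
longitudinal study — the situation faced when tracking a slowly developing
neurodegenerative condition in behaving primates with daily behavioral
sessions and chronic multi-electrode recordings (visual area V4 and
parietal area 7a).

The package computes, per experimental session:

- **Fixation-transition entropy** during visual foraging: with transition
  probabilities `p_ij` from display location *i* to *j* (consecutive
  same-location fixations collapsed into visits),
  `H = −Σ_ij p_ij log₂ p_ij`, z-scored against a within-trial shuffle null,
  `z = (H_actual − μ_shuffled)/σ_shuffled`. Negative z means more
  structured scanning than chance; z ≈ 0 means approximately random
  foraging.
- **Gap-task superfluous-saccade rate** — the fraction of trials with an
  unrewarded saccade leaving the 1.0° fixation window between fixation-spot
  offset and target onset (a failure of oculomotor inhibition), plus
  foraging (reward/fixation, inter-fixation distance, revisit rate) and
  preferential-looking metrics (novelty preference, image switches,
  fixation durations).
- **Firing-rate-matched noise correlations** (r_SC): Pearson correlation of
  trial-to-trial spike counts in a 200 ms stable-fixation window, averaged
  over simultaneously recorded pairs, after subsampling units so the mean
  baseline rate lies in 20–30 sp/s.
- **Intrinsic timescales**: the decay constant τ of `A·exp(−lag/τ) + B`
  fitted (from 3 ms after zero lag) to the shuffle-corrected,
  mean-rate-normalized spike-count autocorrelogram; units kept only when
  R² > 0.5.
- **Leave-one-out population decoding**: ridge regression with neurons as
  regressors, scored as the Pearson correlation between held-out
  predictions and the true stimulus feature; plus **QR-orthogonalized
  color/shape population axes** and a dimension-**ablation** analysis for
  arbitrary feature matrices.
- **Longitudinal trend tests**: per-metric F-tests of a fitted slope
  against the constant null, and a segmented pre/post-treatment slope
  comparison that allows an intercept jump at treatment onset.

Because recordings of this kind are rarely shareable, the package ships a
first-class `synthetic_data` module whose generators have analytically
known ground truth for *every* estimator above (structured/random scan
paths, shared-gain Poisson counts with closed-form pairwise correlation,
Ornstein–Uhlenbeck-modulated spike trains with known τ, tuned populations
with a population-level disruption knob, and a drifting one-year study
generator), so the whole pipeline is verifiable end to end.

## Worked example

```python
from popdisorg import (ForagingSimConfig, simulate_foraging_session,
                       entropy_zscore, GainModelConfig,
                       simulate_population_counts, noise_correlations)

structured = simulate_foraging_session(ForagingSimConfig(structure=0.9, seed=1))
random_ = simulate_foraging_session(ForagingSimConfig(structure=0.1, seed=1))
for name, sess in [("structured", structured), ("random", random_)]:
    r = entropy_zscore(sess, n_shuffles=1000, seed=0)
    print(f"{name:>10}: H = {r.H:5.2f} bits, null = {r.mu_shuffled:5.2f} "
          f"+- {r.sigma_shuffled:4.2f}, z = {r.z:+6.2f}")

counts = simulate_population_counts(
    GainModelConfig(n_units=50, n_trials=2000, gain_var=0.01, seed=2))
res = noise_correlations(counts)
print(f"mean rSC = {res.mean_rsc:.4f} over {res.n_pairs} pairs "
      f"(model closed form {counts.meta['rho_true'][0, 1]:.4f})")
```

prints

```
structured: H = 14.61 bits, null = 24.67 +- 0.45, z = -22.58
    random: H = 24.29 bits, null = 24.34 +- 0.42, z =  -0.11
mean rSC = 0.0499 over 1225 pairs (model closed form 0.0476)
```

The structured forager scans the array far more predictably than its
shuffle null (z = −22.6), the near-random forager sits at chance, and the
estimated mean noise correlation agrees with the doubly stochastic model's
closed form.

A command-line interface mirrors the library
(`popdisorg simulate|behavior|neural|trend|run|report`); e.g.

```bash
popdisorg simulate study --out sessions/ --seed 1
popdisorg run sessions/ --out results/
popdisorg report results/ sessions/ --out figures/
```

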