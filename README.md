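# vmchoice

Synthetic-data pipeline for studying how a value-comparison signal in
ventromedial prefrontal cortex (vmPFC) can be read out from macaque
fMRI — and why its sign can invert relative to the human signal.

## The scientific problem

During a choice between two options, activity in primate vmPFC tracks
the decision variable *chosen value − unchosen value*. In humans the
BOLD correlate of this variable is positive; in macaques the same
analysis yields a **negative** coefficient — activity grows as
decisions get *harder* (options closer in value). This package
implements, end to end and on fully synthetic data, the computational
chain needed to study that phenomenon:

1. **Task simulators** for two paradigms:
   a cued "less-is-more" task (120 trials: 90 one-option, 30 choice
   trials; options HV = high-value, LV = low-value, CV = compound of
   both, plus unrewarded stimuli) with agents whose compound valuation
   is biased toward the *mean* of the components,
   `v_CV = λ·mean(v_HV, v_LV) + (1−λ)·(v_HV + v_LV)`, so that
   v_HV > v_CV > v_LV; and a 200-trial three-option probabilistic
   reversal task where two of three stimuli are drawn uniformly each
   trial and reward probabilities drift as reflected random walks.
2. **Subjective value estimation** — empirically, as the offer-weighted
   choice frequency `Σ_contexts p(chosen|context)·n(context) / Σ n`,
   or by fitting a Rescorla–Wagner learner
   `V ← V + α(r − V)` with softmax choice `P(s) ∝ exp(V_s/T)` by
   minimizing the session negative log-likelihood `L = −Σ log P(t, c_t)`.
3. **Synthetic BOLD** through a macaque hemodynamic response (gamma
   kernel, mean 3 s, sd 1.5 s, i.e. shape 4, scale 0.75 s), from either
   a linear event-amplitude model or a two-pool attractor network.
4. **GLM analysis** — categorical (24-column) and parametric (10-column)
   designs with z-scored value-sum and value-difference modulators,
   B-spline high-pass filtering (100 s cutoff), per-session OLS,
   inverse-variance fixed-effects pooling, and two-tailed group tests.
5. **Decision-locked ROI time courses** — spherical-mask extraction,
   epoching with 0.25 s upsampling, per-timepoint regression, and
   leave-one-out peak selection with an exact sign-flip permutation
   test to keep the readout free of selection bias.
6. **Behavioral statistics** — choice frequency vs 50%, RT regressions
   on value sum and difference, and a balanced repeated-measures ANOVA
   with an optional between-subject (e.g. lesion) factor.

The attractor generator demonstrates the sign-flip mechanism: when the
winning population's activity **decays** after the decision, aggregate
activity is dominated by deliberation time and the fitted
value-difference beta is negative (macaque-like); when the winner is
**sustained** in its attractor, the beta moves positive (human-like).
A single post-decision regime switch flips the sign.

## Worked example

```python
from vmchoice import pipeline as pl

cfg = pl.RunConfig(seed=11, out_dir="runs/demo")   # 4 subjects x 4 sessions
pl.run_simulate(cfg)          # event TSVs + JSON sidecars
glm = pl.run_glm(cfg)         # per-session GLM-2, fixed effects, group test
report = pl.run_report(cfg)

print(report["mean_empirical_values"])
print(glm["subject_effects"], glm["group_t"], glm["group_p"])
```

prints

```
{'HV': 0.931, 'CV': 0.829, 'LV': 0.768}
[-0.426, -0.523, -0.716, -0.429] -7.67 0.0046
```

The empirical values reproduce the less-is-more ordering
HV > CV > LV (the compound is worth *less* than its better part), and
every synthetic subject shows a negative value-difference beta near the
planted −0.5: the group test confirms the difficulty-positive signal.
The sign-flip demonstration:

```python
pl.sign_flip_betas(n_trials=500, seed=11)
# decay regime beta: -0.373   sustain regime beta: +0.743
```

The same CLI is available as `vmchoice simulate|fit-rl|glm|timecourse|report`
with `--config run.yaml`, `--seed`, and `--out` flags.

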