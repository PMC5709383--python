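# Methods

This note documents the models implemented in `vmchoice`, the defaults
and the reasoning behind them, what the synthetic data do and do not
emulate, and the numerical choices that matter for reproducing results.

## Task simulators

**Cued one-/two-option task.** A session has `n_trials = 120` with
`p_single = 0.75`: the single-option count is `round(n·p)` (banker's
rounding at exact ties) and the remainder are choice trials, so the
default session is exactly 90 + 30. Single-option trials cycle through
the three rewarded stimuli; choice trials are split between CS+/CS−
pairs and CS+/CS+ pairs by `p_choice_csminus` (default 0.5 — the
published schedule description is arithmetically ambiguous between "15%
of all trials" and "15% of choice trials", so the split is a
configuration knob rather than a constant). The order is then
shuffled. Inter-trial intervals are uniform on 5–7 s; the
response-to-outcome delay is uniform on 4 ± 1 s; the outcome phase
lasts 3 s. Event times therefore strictly increase within a session.

**Agents.** A `SubjectiveAgent` holds values for HV, LV and the
unrewarded stimulus and derives the compound value by interpolating
between the mean (`cv_bias = 1`) and the sum (`cv_bias = 0`) of the HV
and LV values. The default `cv_bias = 1` produces the control-animal
ordering v_HV > v_CV > v_LV; a lesion-like agent is obtained by
lowering `cv_bias` toward 0.5, which moves HV-vs-CV choices toward
indifference. Choices are softmax with temperature 0.25 (default
values 0.95 / 0.6 / 0.1 give single-option take rates near the 77–92%
range seen in well-trained animals). One-option trials are modeled as
a softmax between the offered value and a fixed skip value (default 0).

**Reaction times.** RT = intercept + b_sum·(v_c+v_u) + b_diff·(v_c−v_u)
+ Gaussian noise, truncated at a 250 ms floor (truncation, not
resampling, so extreme draws pile up at the floor rather than changing
the noise law). Defaults: intercept 1000 ms, b_sum = −100, b_diff = −50,
noise sd 100 ms — both slopes negative, i.e. faster responses when the
options are valuable and easy to discriminate.

**Three-option reversal task.** 200 trials; on each trial 2 of 3
stimuli are drawn uniformly without replacement (hence the chosen
stimulus reappears on the next trial with probability exactly 2/3).
Reward probabilities follow independent reflected Gaussian random walks
(start U[0.2, 0.8], step sd 0.03 per trial, reflecting bounds
[0.1, 0.9]); these walk parameters are our choice of a slow drift that
forces continued learning without pinning probabilities at the bounds.
Choices come from a stateful Rescorla–Wagner learner.

## Learning model and fitting

Values update by the delta rule `V[t+1,s] = V[t,s] + α(r_t − V[t,s])`
for the chosen s only; choice probabilities are
`P(s) ∝ exp(V_s / T)`. The softmax is normalized over the two options
actually offered on a trial; normalization over all three stimuli is
available via `denominator="all"` (the two conventions coincide only
when all stimuli are offered). Initial values are 0.5 for all stimuli —
the uninformative midpoint of the 0/1 reward scale.

The session negative log-likelihood is minimized by L-BFGS-B within
α ∈ [0.01, 0.99] and T ∈ [0.01, 10], from Latin-hypercube starts
(default 10; temperatures are started below 1 because higher starts fit
pure noise). The likelihood tolerance is 1e-8; the reported NLL is
never above any evaluated start (a safeguard against optimizer
failure, with `converged=False` flagging a fallback). The inner
likelihood loop is written in plain Python floats, which is an order of
magnitude faster than per-trial numpy calls at these problem sizes. At
200 trials the suite measures median absolute recovery errors within
0.1 (α) and 0.05 (T) and an α true-vs-fit correlation above 0.7 over a
U[0.1,0.7] × U[0.05,0.5] parameter grid; α is mildly attenuated at low
T, which the recovery test prints as an informative bias line.

## Empirical valuation and regressors

A stimulus's empirical value is its offer-weighted choice proportion
over contexts (vs blank side, vs CS−, vs each other CS+), which equals
total-chosen / total-offered; each presentation counts once. Values
are kept on the [0, 1] proportion scale everywhere; percentages are
formed only at reporting boundaries. Every choosable option receives a
value: CS− stimuli from their own offer/choice counts, the blank-side
skip at a configured value (default 0).

Per-trial chosen/unchosen values are looked up without reordering (the
chosen value may be the lower one). The parametric regressors z-score
the chosen value, the unchosen value, their sum and their difference
*independently, per session*; the difference is formed on raw values
first and then standardized, so `diff_z` is not `chosen_z −
unchosen_z`. Z-scoring (rather than an unspecified "normalization")
makes betas comparable across sessions. A zero-variance vector is an
error, except the value *sum* (our addition beyond the three contracted
regressors), which degrades to a null column with a warning. One-option
trials enter the value regressors with the skip value as the unchosen
value.

## BOLD forward models

**HRF.** A gamma density with mean 3 s and sd 1.5 s (shape
k = mean²/sd² = 4, scale θ = sd²/mean = 0.75 s), evaluated at bin
centers on a `dt = 0.1 s` grid over 20 s and normalized to unit sum.
The "1.5 s variation" is read as the standard deviation; an FWHM
reading is available via `sd_is_fwhm=True`. With the unit-sum
convention a unit delta event produces a response peaking near 0.03
signal units; default noise sds (white 0.015, AR(1) ρ = 0.3 with sd
0.01, cosine drift 0.03 at 300 s period) are set on that scale so that
per-session effects are detectable but noisy, as in real sessions.

**Linear generator.** Each decision event's amplitude is
`β0 + β_diff·diff_z + β_sum·sum_z` (defaults 1.0, −0.5, 0 — the
negative difference beta is the macaque-like, difficulty-positive
direction); outcome events add their own amplitude, optionally
modulated by the chosen value (off by default, nothing is asserted
about it). Events are deltas convolved at `dt` resolution and sampled
at TR = 2.28 s by linear interpolation; the operation is exactly linear
in amplitudes. A voxel-grid variant places the effect in a Gaussian
blob (σ = 1.5 voxels, ~3-voxel radius) for the spatial
leave-one-out analysis.

**Attractor generator.** A reduced two-variable rate model: two
rectified leaky accumulators with self-excitation (w₊ = 3.0), mutual
inhibition (w₋ = 2.5), leak 3.0 s⁻¹, input gain 4.0 on the option
values, additive noise (sd 0.8·√dt per Euler step, dt = 5 ms), baseline
1 and threshold 6. These constants were calibrated once so the mean
decision time is ≈1 s when option values are far apart, rising as they
approach (and they produce essentially no undecided trials at the
4 s deadline; exact ties break by a seeded coin flip). After threshold
crossing the *decay* regime relaxes both pools to baseline while
*sustain* holds the winner at threshold until trial end. The per-trial
regressor amplitude is the integrated above-baseline activity of both
pools. Under decay, integrated activity is dominated by deliberation
time — longer for close values — so the fitted chosen−unchosen beta is
negative; under sustain, post-decision maintenance rewards *fast*
(easy) decisions with more integrated activity, pushing the beta up.
The suite asserts the ordering (decay < 0 and decay < sustain), not a
specific positive value.

## GLM engine

GLM-2 (parametric): four event regressors (CS+-chosen cue and outcome,
no-CS+ cue and outcome), two parametric modulators (sum_z, diff_z) on
the CS+-chosen cue events, and four response regressors (left/right,
convolved and unconvolved) — 10 columns. Modulators are mean-centered
per session before convolution, making them orthogonal to their parent
column when event responses do not overlap. GLM-1 (categorical): nine
provisional decision-type × choice conditions (three single-option
takes, single-option skip, CS− pair with CS+ or CS− taken, and the
three CS+ pairs) plus a discarded-trials regressor, each at cue and at
outcome, plus the four response regressors — 24 columns. Empty columns
(conditions absent from a session) are dropped with a warning and
recorded on the design object. Cue/outcome event durations are 0
(deltas).

High-pass filtering residualizes data and design identically against a
cubic B-spline drift basis with knots every cutoff/3 seconds (cutoff
100 s). A discrete-cosine basis was tried first and rejected: it
leaves ~20% edge residual on a 200 s-period drift, while the spline
basis leaves <1% everywhere and passes event-speed signal essentially
untouched. Degrees of freedom subtract the basis dimension. OLS is
solved by the normal equations after rank-pruning duplicate columns;
contrasts use t = c'β̂ / √(c'(X'X)⁻¹c·σ̂²), two-tailed. Sessions pool
within subject by inverse-variance weighting; the group test is a
two-tailed one-sample t across subjects — a deliberate simplification
of hierarchical mixed-effects inference, adequate for planted-effect
recovery and calibration checks on synthetic data.

The signed-vs-absolute analysis enters the z-scored chosen−unchosen
difference and the z-scored |difference| jointly on the decision
events, reports their correlation, and refuses to fit above |r| = 0.9.
Softmax-driven errors make the two regressors decorrelate (r ≈ 0.5 at
temperature 0.25), which is what lets each effect be identified while
the other's CI covers zero.

## Time-course analysis

ROI extraction averages voxels within a Euclidean-distance sphere
(radius 2 → 33 voxels on the integer lattice). Epochs cover −2 to
+14 s around decision onset, linearly interpolated to a 0.25 s grid —
linear interpolation is exact for linear signals and keeps epoching and
averaging commutative; no baseline correction is applied by default
(pre-event mean subtraction is a config option). Edge events are
dropped and logged. Per-timepoint OLS across trials (intercept +
diff_z + sum_z, optionally RT) yields beta time courses.

Leave-one-out peak selection picks, for each fold, the extremum of the
*other* sessions' mean course (|mean| for effects of either sign, with
the sign recorded; a literal-maximum mode is available) and reads out
the held-out session there; the spatial variant applies identical fold
logic to flattened per-session voxel maps. Two p-values are returned.
The naive one-sample t on the fold values is unbiased in its *estimate*
(each value is selected without seeing its own session) but remains
anticonservative when selection is noise-driven, because the folds
share their selection and are positively correlated — the suite
measures both this inflation and the far larger inflation of circular
same-data selection. The recommended inference is therefore an exact
sign-flip permutation test that re-runs the entire selection under all
2ⁿ session sign patterns; it is exact under sign-symmetric session
noise. Because a global sign flip leaves |t| unchanged the flip
distribution has 2ⁿ⁻¹ distinct values, so at α = 0.05 the test is
conservative with 6 sessions (attainable level 1/32) and close to
nominal with 8 (6/128 ≈ 0.047).

Trial-peak analysis takes each trial's epoch maximum in the 1.5–6.5 s
post-stimulus window and tabulates cell means by chosen × unchosen
option; factorial inference on per-subject cell tables goes through the
repeated-measures ANOVA below.

## Behavioral statistics

Choice percentages are tested against 50% with a two-tailed one-sample
t (raw percentages, untransformed); zero-variance inputs return a
flagged degenerate result rather than an exception. RT regressions fit
each session by OLS on value sum and signed difference, average
coefficients within subject, and test them across subjects.

The repeated-measures ANOVA is a classical balanced sums-of-squares
decomposition with subject as a random factor nested in an optional
between-subject group: group is tested against subjects-within-groups;
every within effect (and its interaction with group) against its
interaction with subjects. The strata sum exactly to the total SS and
the implementation is cross-checked against pingouin on the designs
that package supports; it was written in-house because no installed
package fits multiple within factors *and* a between factor.
Unbalanced or incomplete tables raise with the offending cells listed.
A square-root response transform is available. No sphericity
correction is applied; uncorrected degrees of freedom are reported with
a warning (the correction changes dof, not the decomposition, and
cannot be reproduced without the original data).

## What the synthetic data do not emulate

The generators produce event-locked signals with stationary AR(1) +
white noise and smooth drift; they contain no physiological noise
structure, motion, spatial autocorrelation, susceptibility artifacts,
or preprocessing residue, and the behavioral agents have no satiety
dynamics, lapses, or session-to-session learning carryover. Passing
tests therefore certify the *analysis chain* — equations, estimators,
calibration, selection-bias control, and the attractor mechanism — not
the claim that real tissue or real animals behave this way.

## Problem sizes used by the suite

The acceptance-style checks run at sizes a laptop CPU handles in
seconds: 12,000 reversal trials for the re-offer rate; 100 replicates
of 200-trial sessions for parameter recovery; 500 replicates for GLM
coverage and 1,000 for type-I calibration (40-event sessions); 1,000
simulations of 8-session null time courses for the selection-bias
check; 500 attractor trials per regime; 300 replicates per direction
for signed-vs-absolute specificity. These sizes were chosen to make
Monte-Carlo error small relative to the asserted bands. Coverage and
type-I calibration simulations use pure white noise, where OLS
intervals are exact; autocorrelated noise and drift are exercised by
the filtering tests and the end-to-end pipeline demo instead, since
naive OLS intervals are only approximate under AR(1) noise.
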