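# Methods

`varisk` implements, end to end, the computational chain linking a baited
two-object matching task to neuronal codes for economic risk derived from
reward experience: task simulation, history-weighted subjective decision
variables, risk-sensitive choice models with model comparison, synthetic
spiking populations with known tuning, a single-neuron regression battery,
and pseudo-population decoding.  Because every analysis runs on synthetic
data with known ground truth, correctness is assessed by calibration (null
data produce nominal false-positive rates) and recovery (designed
parameters, tuning categories and latencies are re-identified).

## Task model

Two objects A and B carry block-wise base reward probabilities `P0_A + P0_B
= prob_sum` (default 0.6; each member on the admissible 0.05-step grid in
[0.05, 0.55]), with block lengths drawn uniformly on [50, 150] trials and no
immediate block repeats.  Reward is scheduled by a bait-and-persist state
machine: each trial every unbaited object becomes baited with its base
probability, and the bait persists until the object is chosen.  The marginal
availability after `n` consecutive unchosen trials is then

    P = 1 - (1 - P0)^(n + 1),

which the simulator verifies as an emergent property rather than sampling it
directly; this realization also captures the fact that an assigned reward
remains available until collected.  The instantaneous probability is
recorded clamped to [0, 1]; the unchosen counter keeps incrementing while
the bait flag saturates, which is harmless.  Cue position (side of object A)
is counterbalanced in shuffled blocks of four.  Event times are drawn from
the task's stated jitter windows (fixation period 1.0-2.0 s, alert cue
0.7-1.0 s, alert-to-cue gap 1.4-2.0 s, saccade latency 0.25-0.75 s), which
matters only for spike-time simulation and sliding-window analyses.

Objective (variance) risk of choosing an object with instantaneous
probability `p` and fixed reward magnitude `m = 0.7` ml is the Bernoulli
outcome variance `p (1 - p) m^2` (ml^2), the standard two-outcome variance;
it reproduces the stated maximum 0.1225 ml^2 at `p = 0.5` and is an
inverted-U function of probability.

## Subjective decision variables

The influence of past outcomes on choice is estimated by logistic regression
of current object choice on reward-difference and choice-difference
regressors over the last `N = 10` trials (reward indicator = chosen AND
rewarded; burn-in = the first N trials, excluded from every downstream fit).
The fitted reward weights `b_r[j]` and choice weights `b_c[j]` define

* value (reward history):      `OV_r  = sum_j b_r[j] R(i-j) / N`
* value (reward + choice):     `OV_rc = (sum_j b_r[j] R + sum_j b_c[j] C) / N`
  (a single denominator N over both sums, as the construction prescribes)
* subjective risk:             `var = sum_j b_r[j] (R(i-j) - mean)^2 / (N-1)`

with `mean` the *unweighted* window mean of R; a weighted-mean variant is
available behind a flag but is not the default.  Negative fitted weights are
used as-is; rare negative risk values are retained.  Action-domain values
and risks use action-referenced indicators and weights refit on action
choice — they are not re-labelled object quantities.  All implementations
are vectorized convolutions, tested to 1e-12 against loop-based oracles.

The headline choice model is a logistic regression of side choice on
left-right differences of `OV_rc` and `var` (plus a side-bias intercept); a
positive risk weight means risk seeking.  Mean-variance utility per object
is `U = b1 OV_rc + b2 var` with the weights taken from that fit.
Separation or non-convergence in any logistic fit falls back to a lightly
ridge-penalized binomial GLM, flagged on the result object.

## Model comparison

Eleven candidate models are ranked by AIC/BIC: history-value logits (reward
history, choice history, both; each with and without risk), objective
probability/risk logits, and three Rescorla-Wagner variants (standard;
"stack", in which the unchosen option's value grows toward 1 at a free rate,
mimicking bait accumulation; "reversal", updating the unchosen option toward
the complementary outcome).  RL likelihoods are maximized on an
unconstrained scale (logit learning rates, log inverse temperature) with
bounded multi-start L-BFGS-B; natural-scale standard errors come from the
numerical Hessian by the delta method.  All likelihoods are evaluated over
the same post-burn-in trials, and AIC/BIC are reported on a per-trial mean
deviance scale, so values are comparable across models of both families
(object- and side-frame likelihoods are interchangeable because the mapping
between object and side choice is a per-trial bijection given cue position).
Second-stage parameter counts only are penalized for the history-value
models; the first-stage weight fit is shared by all of them.

Matching behavior is summarized by the block-wise regression of log choice
ratio on log reward ratio (0.5 additive smoothing for zero counts; exclusive
preference flagged as degenerate), a seven-trial sliding choice/reward
fraction trace, and value-bin x risk-split psychometric tables in which the
risk median split is computed *within* each value bin so that it is not
confounded by the strong value-risk correlation.

## Synthetic neurons

Each neuron's per-epoch rate is `baseline * drift + sum_v gain_v * z_v`,
floored at zero, with Poisson counts over the 11 canonical 500-ms epochs
(Pre-fix ... Outc2; Pre-fix is the control period).  Variables are z-scored
inside the rate model so gains (impulses/s per z-unit) are comparable across
variables, mirroring standardized regression coefficients; tuning signs are
drawn +/-1 per neuron by default since real populations code risk with both
slopes.  Optional drift is an AR(1) process on the log baseline.  For
time-resolved analyses, spike times are generated from a piecewise-constant
rate across the whole trial, with tuning switched on inside epoch windows or
inside explicit time windows (e.g. a designed history -> risk -> choice
sequence with staggered onsets).  Epoch counts and spike times are separate
draws unless counts are obtained by binning the simulated spike stream.

What the generator does *not* emulate: non-Poisson count dispersion,
within-trial rate autocorrelation beyond the designed windows, cross-neuron
noise correlations (the decoder deliberately ignores them), and any
oculomotor or reward-delivery artifacts.  Passing tests therefore show that
the analysis battery is correct and calibrated for linear-Poisson neurons,
not that real neurons satisfy those assumptions.

## Neuronal analysis battery

Task-relatedness: paired Wilcoxon of each epoch against Pre-fix, two-sided,
p < 0.005 Bonferroni-corrected over the 10 test epochs; the control period
itself is always admitted.  Responses (neuron x epoch) are then fit by OLS
on raw impulse rates with per-coefficient two-sided t-tests at p < 0.05.
Regressor sets cover objective risk, subjective risk, last-trial and
two-trial history, action risk, competition sets for stepwise selection, and
a utility control in which utility regressors replace value regressors.
Standardized slopes are `b * s_x / s_y`; per-regressor partial R^2 is
`(SSE_reduced - SSE_full) / SSE_reduced`, computed via the equivalent
`t^2 / (t^2 + df)` identity and tested against explicit nested refits.

Angle classification fits activity on the two risk regressors only; if the
overall F-test is significant (p < 0.05) the polar angle of the coefficient
pair assigns one of eight half-open 45-degree segments
(`[center - 22.5, center + 22.5)`, so a boundary angle joins the upper
segment): 0/180 degrees = first-alternative risk, 90/270 = second, 45/225 =
risk sum, 135/315 = risk difference.  Stepwise regression uses forward entry
at p <= 0.05 and backward removal at p >= 0.10 from an empty model.  A
partial F-test asks whether a distinct choice regressor improves a response
model; proportion contrasts use a McNemar-style z-test for dependent
samples.

Sliding-window regression uses 200-ms windows stepped by 25 ms.  Windows
slide within event-aligned segments; the default is the fixation segment
(-500 to +1000 ms around fixation onset), the longest span over which every
trial is guaranteed to be in the same task phase given the event jitters
(the alert cue can appear from +1000 ms).  Later segments (cue-, fixation-
offset-, cue-offset- and outcome-aligned) tile the rest of the trial, and
significance runs never cross segment boundaries.  A variable counts as
coded when more than six consecutive windows are significant at p < 0.05;
response-label trial shuffling reproduces the criterion's calibration — on
untuned Poisson data the fraction of shuffled runs passing is about 4.3%,
below the 5% bound.  Because 200-ms windows at 25-ms steps overlap heavily,
adjacent-window statistics are correlated (count correlation = overlap
fraction), which is exactly why the run criterion needs shuffle calibration
rather than a naive independence argument.  Coding latency is the start of
the first qualifying run; latency orderings are compared by rank-sum tests.

Population curves z-score activity against the control period, sign-correct
each neuron by the sign of its slope on a designated variable, and average
within equal-population value bins.  The inverted-U of risk-neuron activity
over value appears when value bins span the reward-rate range across 0.5
(the variance of a binary reward window peaks at mean 0.5); under matching
behavior with base probabilities capped at 0.55, window reward rates rarely
exceed 0.5, so the descending branch is demonstrated with a designed
reward-rate sweep rather than simulator sessions.  Risk updating contrasts
each neuron's cue-period activity on trial N against N-1 for trials whose
preceding reward increased vs decreased the relevant risk variable, with a
Wilcoxon signed-rank across neurons.  Non-stationarity controls refit the
response model with a previous-trial-rate autoregressive term and,
separately, on control-period-subtracted activity.

## Decoding

Trials are split into rank-based terciles of the grouping variable (ties
broken stably; a median-split variant is available); low vs high tercile
population vectors of control-z-scored rates are classified by a linear SVM
(C = 1) or a 1-nearest-neighbor classifier.  Neurons are matched randomly
across trials within groups (independently recorded units), down-sampled
without replacement to the common minimum group size, with a minimum of
eight trials per group for inclusion; accuracies are averaged over matching
iterations.  Cross-validation is leave-one-out with per-fold training
rebalancing: one randomly chosen opposite-class trial is dropped alongside
the held-out trial, because plain LOO on balanced data leaves the held-out
class under-represented and biases null accuracy ~2 percentage points below
chance.  With rebalancing the group-label-shuffle null is centred on 50%.
Chance is 50% by construction (balanced groups).

## Problem sizes and numerical choices

Defaults chosen once as the study conditions: history length N = 10; value
sensitivity beta1 = 20 and risk weight beta2 = +2 for the generative
value/risk agent (beta1 calibrated so the agent's block-wise matching slope
is ~0.85, the near-matching regime the task produces in practice; beta2
positive = risk seeking, the attitude the task elicits); exponential history
weights 1.5 e^{-j/2} (reward) and 0.8 e^{-j/2} (choice); RL agent alpha =
0.3, tau = 5.  Recovery suites use 10,000 trials for behavioral parameters,
5,000 trials x 20 replicates for model recovery, 500 trials and gain 6
impulses/s/z for neuronal recovery, and reduced decoding iterations
(30 matchings, 500 shuffles); the within-family model-recovery check uses a
generative risk weight comparable to the value weight (beta1 = 10, beta2 =
20), since at beta2 = 2 the risk term's AIC contribution is genuinely
marginal against the nested no-risk model.  All randomness flows through
explicit numpy Generators; identical seeds reproduce sessions, spikes and
accuracies byte-for-byte.

## Known limitations

Absolute AIC/BIC magnitudes of published model-comparison tables are not
reproducible (their likelihood normalization is not recoverable); the
comparison here is about ranking, on a per-trial deviance scale.  The
subjective value and risk regressors are strongly correlated by
construction (both derive from the same reward window), so risk-weight
standard errors are wide and within-family model selection requires either
many trials or a strong risk effect — matching what the task's statistics
impose on any analysis of it.  Sessions are fitted independently; there is
no hierarchical pooling, no reaction-time modelling, and no biophysical
spiking model.
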