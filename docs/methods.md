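# Methods

## Scope and model set

`choicekit` models trial-level choice in two task families:

* **K-armed Bernoulli bandits**: on trial *t* the chosen arm *k* pays 1
  with probability μ<sub>t</sub><sup>k</sup>, else 0.  Stationary tasks
  (`make_bandit_task`), and blocked reversal designs
  (`make_reversal_task`) in which the per-arm means alternate across
  blocks and agents treat each block as an independent bandit.
* **Deterministic stimulus–action tasks** (`StimulusTaskConfig`): one of
  S stimuli is shown per trial and exactly one action is rewarded for it.
  The default instantiation has 3 stimuli and 3 actions with map
  (s1→a1, s2→a1, s3→a3), so one action is never correct and a
  stimulus-blind policy can reach at most 2/3 accuracy.

Only the chosen option's outcome is realised; no counterfactual outcomes
exist anywhere in the pipeline.  Rewards are strictly binary.

The candidate models (`M1`, `M2`, `M3`, `M4`, `M5`, `M3-bias`,
`blind-RL`, `state-RL`) are described in the README.  Within a trial the
event order is fixed: compute choice probabilities from the current state,
sample (or read) the choice, realise the reward, then update the state.
Updates therefore first affect the *next* trial.  Two modeling
conventions deserve note:

* **M2 first trial.**  Noisy win-stay-lose-shift is defined in terms of
  the previous trial; with no previous outcome (session or block start)
  the model chooses uniformly, the least-informative completion.
* **Choice kernel.**  The kernel updates *every* option each trial with
  the chosen-option indicator as the target, so unchosen options decay
  toward zero.  With α<sub>c</sub> = 1 the kernel is a one-back choice
  memory.  Despite the folk equivalence, this is not identical to M2: the
  kernel ignores reward, and both models are implemented literally.
* **M1 and M2 are two-option models.**  They are defined only for K = 2
  and raise an explicit error otherwise rather than silently
  generalizing.

The side-biased model follows
p(left) = 1 / (1 + exp(β(Q(right) − Q(left) − B))): the bias B acts on the
value scale and is multiplied by β inside the softmax.

Initial values Q<sub>0</sub> default to 0 and are a model-construction
option, not a fitted parameter (`get_model("M3", q0=0.5)`); the reversal
recipe uses Q<sub>0</sub> = 0.5 so that neither arm starts favored within
a block.  When a task or dataset carries block bounds, the model state
(values, kernel, previous outcome) resets to fresh at every block start,
in both simulation and likelihood evaluation.

## Parameters, bounds and priors

| parameter | meaning | support | fit bounds | default prior |
| --- | --- | --- | --- | --- |
| b | option-1 bias (M1) | [0, 1] | [0, 1] | U(0, 1) |
| ε | WSLS lapse (M2) | [0, 1] | [0, 1] | U(0, 1) |
| α | value learning rate | [0, 1] | [0, 1] | U(0, 1) |
| β | inverse temperature | ≥ 0 | [0, 30] | Exp(mean 1) |
| α<sub>c</sub> | kernel learning rate | [0, 1] | [0, 1] | U(0, 1) |
| β<sub>c</sub> | kernel inverse temperature | ≥ 0 | [0, 30] | Exp(mean 1) |
| B | side bias (value units) | ℝ | [−10, 10] | U(−2, 2) |

The β upper bound of 30 comfortably exceeds the range in which β is
identifiable in these designs (roughly 1 < β < 10) while keeping every
exponential finite.  Exponential priors are parameterised by their
**mean** (`ExponentialMean(10)` has mean 10); the class makes the
parameterisation explicit because "Exp(λ)" is ambiguous between rate and
mean readings.  `shift_softmax_priors` translates the β/β<sub>c</sub>
priors upward to move from a high-noise to a low-noise simulation regime.

## Likelihood and fitting

The log-likelihood is the sum over trials of the log probability of the
*observed* choice given the *observed* history — the dataset's own choices
and rewards are replayed through the model's update rules (no choice
sampling).  Numerical guards:

* softmax is computed with max-subtraction, so no inverse temperature in
  bounds can overflow;
* each per-trial probability is floored at `prob_floor` (default 1e-12,
  configurable in (0, 1e-6]) before the log, so the objective is finite
  everywhere in the bounded box, including α ∈ {0, 1}, β = 0, ε ∈ {0, 1},
  b ∈ {0, 1}.  The floor only binds when a model assigns an observed
  choice essentially zero probability, where the fit is hopeless anyway;
  the induced bias is negligible.

The inner loops are numba-compiled; the first call in a session pays a
one-time compilation cost of a few seconds.

`fit_mle` runs L-BFGS-B from `n_starts` random initial points drawn from
the model's priors (the same distributions used for recovery
simulations, so starts cover the plausible region), with a bounded
Nelder-Mead fallback for any start that fails or ends non-finite — the
objective is procedural, so a gradient-free path must exist.  Every start
is recorded; per-start seeds derive deterministically from the options
seed.  The default of 10 starts is justified empirically per fit via
`multistart_diagnostics`, which tabulates the running-best log-likelihood
and the parameter distance to the final best as starts accumulate; a flat
tail indicates enough starts.  Fitted parameters within 1e-6 of a bound
are flagged on the result (`at_bounds`) — often, though not always, a red
flag.  A model parameter with no likelihood influence is a definition
error, not a fitting-time discovery: each model declares exactly the
parameters its rules use.

## Model comparison and recovery audits

BIC = −2 LL + k ln T with the natural log and T the number of choices the
likelihood sums over.  Ties within 1e-6 go to the model with fewer
parameters.  `model_recovery` builds the confusion matrix
p(fit | simulated) by simulating each candidate under its prior and
selecting per session by BIC; `invert_confusion` applies Bayes rule
(uniform model prior by default) to obtain p(simulated | fit).  Columns
for models that never win are undefined (NaN) and flagged rather than
fabricated.

`recover_parameters` reports Pearson correlation as the headline recovery
statistic, plus Spearman (β recovery is nonlinear at the extremes), mean
signed bias, and the correlations *among* fitted parameters, which expose
trade-offs even when marginal recovery looks acceptable.  Restricting the
simulation prior to the empirically relevant range is a supported mode —
recovery should be judged where the real fits live.  "Good" recovery for
the learning rate is operationalized as r ≥ 0.8 within 1 < β < 10; the
threshold is a package convention, not a derived quantity.

`compare_nested_recovery` quantifies the nuisance-parameter effect: data
are simulated from the bias-including model on the reversal design
(10 blocks × 50 trials, Q<sub>0</sub> = 0.5) and fit both with and without
the bias.  Generating priors for this recipe — α ~ U(0,1), β ~ Exp(mean
5), B ~ U(−2, 2) — were chosen once: β centred in the identifiable range,
biases comparable to the value scale.  The direction of the β error in
the bias-omitting fit is regime-dependent (a very large bias produces
near-degenerate choice sequences that *inflate* β); the attenuation
effect — bias mistaken for noise — is demonstrated at moderate bias
magnitudes (|B| ≲ 0.6).

## Validation and latents

`stay_probability` and `performance_curves` are the model-independent
measures: the former conditions repetition on the previous trial's reward
(block-crossing pairs excluded), the latter defines "correct" as the
uniquely best option per trial and reports early/late windows of 10
trials by default.  `average_trial_likelihood` is the geometric mean
exp(LL/T) — equal to 1 only under perfect prediction — with the
arithmetic mean exposed alongside since either convention appears in
practice; comparisons in the validation recipe use the geometric mean.
`one_step_predictions` conditions on the subject's actual history and is
deliberately distinct from `posterior_predictive`, which simulates the
fitted model freely and compares summary measures with central-95%
simulation bands.  `extract_latents` replays the subject's choices
through the model (yoked), recording values, kernels, prediction errors
and choice probabilities before each update; it is deterministic in
(dataset, parameters).

The stimulus-task validation recipe (`box7`) uses two frozen synthetic
agents: a low-noise blind learner (α = 0.3, β = 8) and a high-noise
state-based learner (α = 0.35, β = 1.5) on 300 trials.  These values were
tuned once so the two agents' session-average learning curves agree
within 0.05, then frozen; the qualitative phenomenon — the state-based
model predicts the *wrong* agent's choices with higher trial likelihood,
while posterior predictive simulation exposes the mismatch by
overshooting the blind agent's curve — does not depend on the fine
tuning.  The default stimulus schedule is a seeded permuted-block
sequence (every consecutive group of S trials shows each stimulus once),
so that windowed accuracy measures compare like with like; a fully
uniform random schedule can be supplied explicitly.

## What the synthetic data do and do not emulate

All test inputs are generated by the task simulators and the models
themselves.  The generators reproduce the study conditions exactly as
specified — session lengths, reward probabilities, priors — but they are
ideal agents: stationary parameters, no attention lapses beyond the
modeled ones, no response-time structure, no within-session drift, and
the generating model is always in the candidate set.  Passing audits on
such data is therefore a *best case*: it shows the pipeline is sound, not
that real behavior is as recoverable.  Conversely, failures on synthetic
data (e.g. the M5 confusion under high noise) are lower bounds on the
trouble real data will cause.

## Problem sizes

The acceptance script runs the confusion-matrix experiment at its full
size (5 models × 100 sessions × 1000 trials, 10 optimizer starts per
fit; a few minutes on one CPU).  The test suite runs the same audit at
50 sessions and 5 starts per model with correspondingly wider
tolerances, parameter recovery at 200 replicates, and the nuisance-bias
comparison at 100 replicates — sizes at which each qualitative effect is
stable across seeds while the whole suite stays fast.

## Limitations

* Maximum-likelihood only: no MAP, MCMC, hierarchical/random-effects
  fitting, or exceedance probabilities; no AIC or cross-validation
  scoring.  BIC is the single comparison metric.
* No Hessian-based standard errors on fits; uncertainty is assessed by
  recovery simulation.
* No drifting/random-walk reward schedules, graded rewards, or
  response-time modeling.
* Identifiability is audited empirically, not analytically (no profile
  likelihood or Fisher information).
* The working-memory + reinforcement-learning hybrid family is out of
  scope; the multistart diagnostics are demonstrated on M5, where strong
  multimodality is not guaranteed.
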