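# Methods

## Task and generative model

Each trial presents two stimuli. In *combined* trials both carry a colored
circle and a ring of 12 Landolt Cs; *Cs-only* and *color-only* trials carry
one component. Reward is Bernoulli with probability
`(p_color + p_cs)/2` on combined trials, where `p_cs` maps the up-count
{3, 6, 9} to {0, 0.5, 1}; single-component trials use the present
component's probability alone. The default schedule is three blocks:
blocks 1–2 each introduce three colors (probabilities 0, 0.5, 1,
assignment counterbalanced per participant by seed) with 36 combined, 18
Cs-only and 18 color-only trials; block 3 has 162 combined trials over all
six colors. Fully identical left/right pairs (same color and same
up-count) are resampled by default so that an accuracy criterion is always
defined; color-tied pairs are allowed.

The agent makes a sequence of decisions per trial. With `t` the decision
index (t = 1 at the first gather decision; t = k+1 after k fixations):

* **gather vs choose** — logistic in a baseline `alpha_gather`, the
  absolute believed value differences `|dV_Cs|` and `|dV_color|`, and an
  urgency term `beta_time·(1 − tau^t)`;
* **look left/right** — logistic in a side bias, the *signed* value
  differences, and a perseverance term `beta_look_stay·I(last side)`,
  with I = ±1 and 0 on a trial's first fixation;
* **choose** — logistic in `beta_choose·(dV_Cs + omega_color·dV_color)`.

`V_Cs` per side is the expectation of the up-count posterior
(binomial likelihood of the up/down counts fixated so far, uniform prior
over {3, 6, 9}); on combined trials the level values are
{0.25, 0.5, 0.75} (the ring's additive half, with the unknown color half
at its 0.5 marginal), on Cs-only trials {0, 0.5, 1}. Note the binomial
(with-replacement) likelihood never fully concentrates: a complete census
of a 3-up ring leaves ≈ 0.83 posterior mass on level 3.

`V_color` is learned by temporal difference:
`V ← V + η·(r − (V_Cs_chosen + V))` with `η = 1/(epsilon + n/2)`, `n`
counting outcomes for that color *including* the current one (first update
uses `1/(epsilon + 0.5)`); values start at 0. `V_Cs_chosen` is the
agent's *believed* C value at choice time (a switch allows the true-count
value instead). Within a trial the color value is retrieved gradually,
`V_eff = V·(1 − tau_color^t)`; at the group-default rate
tau_color ≈ 0.2324 about 94.6% of the learned value is available during
the second fixation. Color-only trials have no fixation sequence to pace
retrieval against, so their choice rule uses the learned value directly.

Time is discrete (fixation events); the 4 s deadline is represented by the
urgency term plus a hard cap of 24 fixations. If one ring is exhausted the
look decision is forced to the other side; if both are exhausted the agent
must choose. Which C within a side is fixated is uniform over the
not-yet-fixated Cs.

## Likelihood and model variants

The session likelihood factorizes over decision events: one gather factor
per fixation, a look factor when both sides are available, one stop factor
at the observed stopping point (omitted when the stop is forced), and one
choice factor per trial, with belief counts advanced along the observed
fixated Cs. Cs-only trials zero all color predictors; color-only trials
contribute only the choice factor. The uniform within-side C identity is
parameter-free and omitted as a constant, so it cannot affect model
comparison. Probabilities are floored at 1e-12 before logs so importance
weights stay finite under extreme proposals. A readable per-trial replay
and a vectorized event-table implementation coexist and are tested for
equality to 1e-9; short-trial outcome distributions are verified against
an independent brute-force enumeration (sum to 1 within 1e-12).

Three variants are compared: the full model, and reduced variants that
remove the color term — and its weight as a free parameter — from the
gather decision (`no-color-gather`) or the look decision
(`no-color-look`), leaving 12 instead of 13 free parameters.

## Hierarchical fitting

Participant-level parameters are modelled as draws from independent
group-level normals in an unconstrained space: identity for the alpha/beta
weights (prior mean 0, sd 1), probit for omega_color, tau and tau_color
(giving near-uniform priors on [0, 1]), and log for epsilon (lognormal
with mean 2 and sd 2). Fitting is iterative importance sampling: per
iteration each participant receives `n_samples` fresh draws from the
current group distribution, weighted by `exp(session loglik)` (max-shift
normalized); the group means and sds are re-estimated by importance-
weighted moment matching pooled across participants — an EM-style
empirical-Bayes scheme. Iteration stops when the largest hyperparameter
change drops below `tol` (default 1e-2) or at `max_iters` (default 50).
Group sds are floored at 1e-3.

Because session likelihoods are much sharper than the group distribution,
effective sample sizes per participant are small (often single digits);
ESS is reported per participant, the group means nevertheless stabilize
within ~10 iterations, and with thousands of decisions per session the
estimator recovers generating group means and ranks participants well
(recovery correlations for omega_color and alpha_gather exceed 0.5 in the
acceptance runs). Two variance-reduction choices address the estimator
noise: nested variants fitted under one seed share their standard-normal
innovations for common parameters (common random numbers, so
marginal-likelihood noise largely cancels in comparisons), and an optional
final evaluation pass re-estimates the per-participant log marginals at
the converged group distribution with a larger sample.

`iBIC = −2·Σ_j log p(data_j | group) + n_hyper·log(N)`, with the log
marginal estimated as the log mean importance weight, `n_hyper` twice the
number of free parameters, and `N` the count of modeled decision events
(every gather, look and choice factor) across the cohort; `N` is recorded
in the fit so alternative conventions can be recomputed.

## Eye-data processing

Fixation reports (TSV: participant, trial, t_start, duration, x, y; pixels,
origin top-left) are assigned to the nearest C center within an acceptance
radius — default half the center-to-center spacing of adjacent Cs, ties to
the lowest C index — or labeled off-stimulus (retained in the table, never
counted). Repeat fixations on an already-fixated C are discarded within a
trial; running up/down counts per side are then accumulated against the
schedule's ring layouts. Participants with ≤ 75% valid samples are flagged
for exclusion from gaze analyses (strictly-above threshold). The
pipeline's principal oracle: reprocessing simulator-emitted reports must
reproduce the simulator's internal counts exactly.

## Synthetic cohorts

`generate_cohort` draws per-participant parameters from a generating group
distribution, simulates sessions, and emits pixel-level fixation reports
(fixations at C centers plus isotropic jitter, sd = radius/4, clipped
inside the radius so assignment is unambiguous; coordinates reported at
0.01 px). The generating defaults encode the regime the task targets:
alpha_gather ≈ 3, beta_dCs ≈ −1, beta_dcolor ≈ −1.5, beta_time ≈ −4 with
tau ≈ 0.9 (several fixations per trial, declining continue-probability),
value-guided and perseverative looking (beta_look_color ≈ 1.5,
beta_look_Cs ≈ 1, beta_look_stay ≈ 1), beta_choose ≈ 5 with
omega_color ≈ 0.5, fast retrieval tau_color ≈ 0.2324 and epsilon ≈ 1;
between-participant sds are 0.3–1 in unconstrained space. Under these
conditions cohorts reproduce the sampling-side trade-off signatures:
fewer fixations on combined than Cs-only trials, and fixation counts
declining with the learned color-value gap.

One regression signature does **not** transfer from humans to the agent:
the color-by-total-Cs choice interaction. In the agent two forces act on
it with opposite signs. Trials that stop early (few Cs) are those with
large learned color-value gaps, so choices there are proportionally more
color-driven — a negative, selection-driven force, recoverable in the
instant-retrieval limit (tau_color → 0 gives ≈ −0.07 at 30 participants).
But the retrieval schedule applies to choices too, so early-stopping
trials also have *less* of the color value available at choice — a
positive force arising from exactly the same trials. At the fast but
non-instant default retrieval rate the two cancel (group mean ≈ +0.02 to
+0.05 across regimes, including much stronger gather trade-offs), so the
agent does not reproduce the negative interaction that humans show; a
planted-interaction simulation confirms the regression machinery itself
recovers negative interactions correctly. Human behavior plausibly
involves trial-to-trial retrieval variability (color sometimes not
retrieved at all) rather than a deterministic within-trial discount,
which this model family does not express.

What the generator does *not* emulate: fixation durations and saccade
kinematics carry no information (fixed 200 ms durations), there are no
off-stimulus or drifted fixations by default (a stress mode widens
jitter), no blinks or tracker loss (validity degradation is injected
explicitly), and real participants surely deviate from the exact
parametric family. Passing tests therefore demonstrate internal
consistency and estimator correctness, not that human data would follow
the model.

## Analyses

Group inference uses a two-stage approximation of crossed random-effects
models: per-participant maximum-likelihood logistic regressions (weak
ridge fallback under separation, flagged) followed by one-sample t-tests
across participants. Predictors are z-scored within participant;
interactions are products of z-scored components (not re-standardized);
`dP(reward|color)` is the running proportion of rewarded outcomes among
prior trials where that color was chosen, 0 before the first. The
relative-use index defaults to the symmetric form
`(β_color − β_Cs)/(|β_Cs| + |β_color|)` (a "caption" variant with
denominator `β_Cs + |β_color|` is available); the model-based index is the
raw ratio `omega_color/alpha_gather`, with negative denominators counted
and near-zero denominators excluded.

## Problem sizes and numerical choices

Acceptance runs use a 30-participant × 306-trial cohort with 2000
importance samples × 12 iterations for parameter recovery, and ten
8-participant × 102-trial replicates at 800 samples × 10 iterations (plus
a 4000-sample evaluation pass) per model-recovery condition; the
enumeration check simulates 50,000 two-fixation trials. These sizes give
stable sign and ranking behaviour at desk scale. Ties in interest-area
assignment go to the lowest C index; degenerate importance weights fall
back to uniform with a warning; zero-variance predictors are flagged and
excluded from normalization.
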