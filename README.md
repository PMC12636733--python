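# gazetrade

Tools for modelling how decisions trade off **learned** information
(reward associations retrieved from memory) against **perceived**
information (evidence sampled by eye movements), in a two-armed bandit
task whose options each combine a colored circle (reward probability
learned by trial and error) and a ring of 12 Landolt Cs (reward
probability instructed to scale with the number of upward-facing Cs —
3, 6 or 9 — which must be resolved by fixating them). The two components
contribute additively and equally to the probability of reward.

The package is aimed at computational cognitive scientists who want to
simulate, fit and analyse this class of gaze-contingent
evidence-accumulation task end to end without any external data: a
synthetic-cohort generator with known ground truth drives every stage.

## The model

Within a trial, an agent repeatedly makes three logistic decisions.
Whether to gather another C or to commit:

    p(continue) = σ( α_gather + β_ΔCs·|ΔV_Cs| + β_Δcolor·|ΔV_color|
                     + β_time·(1 − τ^t) )

where to look, given it gathers:

    p(look right) = σ( α_look-right + β_look-color·ΔV_color
                       + β_look-Cs·ΔV_Cs + β_look-stay·I(looked right) )

and what to choose, once it stops:

    p(choose right) = σ( β_choose · (ΔV_Cs + ω_color·ΔV_color) )

`V_Cs` is the posterior expectation over {3, 6, 9} upward Cs under a
binomial likelihood of the up/down Cs fixated so far; `V_color` is
learned across trials by temporal-difference updates with learning rate
1/(ε + n/2), and retrieved gradually within a trial as
`V_learned·(1 − τ_color^t)`. A negative β_Δcolor produces the paper-style
trade-off: the larger the learned color-value gap, the less perceptual
evidence is gathered.

Participants' parameters are treated as draws from group-level normal
distributions (probit-transformed for unit-interval rates, log for ε)
and fitted by iterative importance sampling — per-participant likelihood
weighting of group-level draws, alternated with importance-weighted
moment matching of the group means and standard deviations. Model
variants (color information removed from the gather or the look
decision) are compared by integrated BIC,
`iBIC = −2·Σ log p(data | group) + n_hyper·log(N decisions)`.

## Worked example

```python
import gazetrade as gz

cohort = gz.generate_cohort(gz.CohortSpec(n_participants=10, seed=3))
fx = gz.fixations_by_trial_type(cohort.participants)
print(fx["table"][["combined", "cs_only"]].mean())
print(fx["combined_vs_cs_only"])
```

prints (seed 3):

```
combined    4.359829
cs_only     5.591667
dtype: float64
{'t': -4.039062037520391, 'p': 0.0029327315270456793,
 'mean_diff': -1.231837606837607, 'n': 10}
```

i.e. simulated participants fixate on average ~4.4 Cs when stimuli also
carry learned colors versus ~5.6 on Cs-only trials — about 1.2 fewer
fixations (paired t = −4.0, p = 0.003): the learned information
suppresses perceptual sampling. Refitting such cohorts recovers the
generating group parameters (see `gazetrade.recovery_harness`), and
`gazetrade.compare_models` ranks the three model variants by iBIC.

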