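"""Generative gather/look/choose agent.

Within a trial the agent repeatedly decides whether to gather more perceptual
information (fixate another Landolt C) or to commit to a choice.  Each
decision is a logistic function of the current evidence:

* gather vs. choose -- baseline tendency, the absolute value differences of
  the C-based and color-based estimates, and an urgency term (1 - tau^t)
  that grows with the number of fixations made this trial;
* look left vs. right -- signed value differences plus a same-side
  perseverance term;
* choose left vs. right -- a softmax (inverse temperature beta_choose) on
  the combined value difference dV_Cs + omega_color * dV_color.

The C-based value of a side is the posterior expectation over the possible
up-counts {3, 6, 9}, with a binomial likelihood of the up/down Cs fixated so
far.  The color-based value is learned across trials by temporal-difference
updates with a learning rate 1/(epsilon + n/2) that decays with the number
of outcomes observed for that color, and is retrieved gradually within a
trial: the effective value is v_learned * (1 - tau_color^t), approaching the
learned value over successive fixations.

The time index t is the decision index: t = 1 at the first gather decision
of a trial and t = k + 1 after k completed fixations, so the value retrieved
"at the second fixation" corresponds to t = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, ndtr, ndtri

from .task import (
    ConfigurationError,
    DataError,
    Side,
    Stimulus,
    TaskConfig,
    TaskSchedule,
    Trial,
    draw_reward,
    true_reward_prob,
)

__all__ = [
    "AgentParams",
    "BeliefState",
    "TrialRecord",
    "PARAM_NAMES",
    "PARAM_TRANSFORMS",
    "constrain",
    "unconstrain",
    "cs_posterior",
    "cs_value",
    "effective_color_value",
    "p_continue_gathering",
    "p_look_right",
    "p_choose_right",
    "td_update",
    "select_c_to_fixate",
    "simulate_trial",
    "simulate_participant",
    "ExhaustionError",
    "DEFAULT_MAX_STEPS",
]

DEFAULT_MAX_STEPS = 24

#: free parameters, in canonical order
PARAM_NAMES = (
    "alpha_gather",
    "beta_dCs",
    "beta_dcolor",
    "beta_time",
    "tau",
    "alpha_look_right",
    "beta_look_color",
    "beta_look_Cs",
    "beta_look_stay",
    "beta_choose",
    "omega_color",
    "tau_color",
    "epsilon",
)

#: unconstrained -> constrained transform per parameter: identity for the
#: alpha/beta weights, the normal CDF for unit-interval rates, exp for the
#: positive learning-rate offset.
PARAM_TRANSFORMS = {name: "identity" for name in PARAM_NAMES}
PARAM_TRANSFORMS.update(
    {"tau": "probit", "omega_color": "probit", "tau_color": "probit",
     "epsilon": "log"}
)


def constrain(name: str, x):
    """Map an unconstrained value to the parameter's domain."""
    t = PARAM_TRANSFORMS[name]
    if t == "identity":
        return x
    if t == "probit":
        return ndtr(x)
    return np.exp(x)


def unconstrain(name: str, v):
    t = PARAM_TRANSFORMS[name]
    if t == "identity":
        return v
    if t == "probit":
        return ndtri(v)
    return np.log(v)


@dataclass(frozen=True)
class AgentParams:
    """The 13 free parameters of the gather/look/choose agent."""

    alpha_gather: float = 0.0
    beta_dCs: float = 0.0
    beta_dcolor: float = 0.0
    beta_time: float = 0.0
    tau: float = 0.5
    alpha_look_right: float = 0.0
    beta_look_color: float = 0.0
    beta_look_Cs: float = 0.0
    beta_look_stay: float = 0.0
    beta_choose: float = 1.0
    omega_color: float = 0.5
    tau_color: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau", "omega_color", "tau_color"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "AgentParams":
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, values)})

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


class ExhaustionError(RuntimeError):
    """All Cs on the requested side have already been fixated."""


# ---------------------------------------------------------------------------
# belief state
# ---------------------------------------------------------------------------

@dataclass
class BeliefState:
    """Evolving state: learned color values plus the within-trial evidence."""

    config: TaskConfig = field(default_factory=TaskConfig)
    v_color_learned: dict[int, float] = field(default_factory=dict)
    n_color_outcomes: dict[int, int] = field(default_factory=dict)
    observed_up: dict[Side, int] = field(default_factory=dict)
    observed_down: dict[Side, int] = field(default_factory=dict)
    fixated: dict[Side, set[int]] = field(default_factory=dict)
    last_side: Optional[Side] = None
    step: int = 0
    current_trial: Optional[Trial] = None

    def __post_init__(self) -> None:
        self._reset_trial_fields()

    def _reset_trial_fields(self) -> None:
        self.observed_up = {"left": 0, "right": 0}
        self.observed_down = {"left": 0, "right": 0}
        self.fixated = {"left": set(), "right": set()}
        self.last_side = None
        self.step = 0

    def begin_trial(self, trial: Trial) -> None:
        self.current_trial = trial
        self._reset_trial_fields()

    # -- per-side quantities -------------------------------------------------

    def color_value(self, side: Side) -> float:
        """Learned value of the side's color (0 when absent or novel)."""
        stim = self.current_trial.stimulus(side)
        if not stim.has_color:
            return 0.0
        return self.v_color_learned.get(stim.color_id, 0.0)

    def posterior(self, side: Side) -> np.ndarray:
        return cs_posterior(
            self.observed_up[side],
            self.observed_down[side],
            self.config.up_levels,
            self.config.n_cs_per_stimulus,
        )

    def cs_side_value(self, side: Side) -> float:
        trial_type = self.current_trial.trial_type
        if trial_type == "color_only":
            return 0.0
        return cs_value(self.posterior(side), trial_type,
                        self.config.up_levels, config=self.config)

    def dv_cs(self) -> float:
        """Signed right-minus-left value difference from the observed Cs."""
        if self.current_trial.trial_type == "color_only":
            return 0.0
        return self.cs_side_value("right") - self.cs_side_value("left")

    def dv_color_learned(self) -> float:
        return self.color_value("right") - self.color_value("left")

    def dv_color_effective(self, tau_color: float) -> float:
        """Retrieval-scaled color difference at the current decision index."""
        t = self.step + 1
        return (effective_color_value(self.color_value("right"), t, tau_color)
                - effective_color_value(self.color_value("left"), t, tau_color))

    def unfixated(self, side: Side) -> list[int]:
        stim = self.current_trial.stimulus(side)
        if not stim.has_cs:
            return []
        return [i for i in range(self.config.n_cs_per_stimulus)
                if i not in self.fixated[side]]

    def side_exhausted(self, side: Side) -> bool:
        return not self.unfixated(side)

    def both_exhausted(self) -> bool:
        return self.side_exhausted("left") and self.side_exhausted("right")

    def apply_fixation(self, side: Side, c_index: int) -> None:
        """Register a (non-repeat) fixation of C ``c_index`` on ``side``."""
        stim = self.current_trial.stimulus(side)
        if not stim.has_cs:
            raise DataError(f"{side} stimulus has no Cs")
        if not 0 <= c_index < len(stim.orientations):
            raise DataError(f"unknown C index {c_index} on {side}")
        if c_index in self.fixated[side]:
            raise DataError(f"repeat fixation of C {c_index} on {side}")
        self.fixated[side].add(c_index)
        if stim.orientations[c_index]:
            self.observed_up[side] += 1
        else:
            self.observed_down[side] += 1
        self.last_side = side
        self.step += 1


# ---------------------------------------------------------------------------
# perceptual inference
# ---------------------------------------------------------------------------

def cs_posterior(observed_up: int, observed_down: int,
                 up_levels=(3, 6, 9), n_cs: int = 12) -> np.ndarray:
    """Posterior over the possible up-counts given the Cs fixated so far.

    Binomial likelihood with a uniform prior over ``up_levels``:
    p(n) propto (n / n_cs)^up * (1 - n / n_cs)^down.
    """
    if len(up_levels) == 0:
        raise ConfigurationError("up_levels must be nonempty")
    if observed_up < 0 or observed_down < 0:
        raise DataError("observed counts must be nonnegative")
    if observed_up + observed_down > n_cs:
        raise DataError("observed more Cs than the ring contains")
    levels = np.asarray(up_levels, dtype=float)
    q = levels / n_cs
    logp = np.zeros(len(levels))
    with np.errstate(divide="ignore"):
        if observed_up:
            logp += observed_up * np.log(q)
        if observed_down:
            logp += observed_down * np.log1p(-q)
    m = logp.max()
    if not np.isfinite(m):
        raise DataError("all up-count levels have zero likelihood")
    p = np.exp(logp - m)
    return p / p.sum()


def cs_value(posterior: np.ndarray, trial_type: str, up_levels=(3, 6, 9),
             config: Optional[TaskConfig] = None, tol: float = 1e-8) -> float:
    """Posterior-expected value of a side's ring.

    In combined trials each up-count level is worth 0.25 + 0.5 * p_cs(level)
    (the ring's half of the additive reward probability, with the color half
    at its marginal expectation); in Cs-only trials the level is worth its
    full instructed probability p_cs(level).
    """
    posterior = np.asarray(posterior, dtype=float)
    if abs(posterior.sum() - 1.0) > tol:
        raise DataError("posterior is not normalized")
    config = config or TaskConfig(up_levels=tuple(up_levels))
    p_cs = np.array([config.cs_prob(n) for n in up_levels])
    if trial_type == "combined":
        weights = 0.25 + 0.5 * p_cs
    elif trial_type == "cs_only":
        weights = p_cs
    else:
        raise DataError(f"no C value in trial type {trial_type!r}")
    return float(posterior @ weights)


def effective_color_value(v_learned: float, step: int, tau_color: float) -> float:
    """Retrieval-scaled color value v * (1 - tau_color^step)."""
    if step < 0:
        raise DataError("step must be nonnegative")
    return v_learned * (1.0 - tau_color ** step)


# ---------------------------------------------------------------------------
# the three decision policies
# ---------------------------------------------------------------------------

def p_continue_gathering(state: BeliefState, params: AgentParams,
                         include_color: bool = True) -> float:
    """Probability of gathering another C rather than choosing now."""
    t = state.step + 1
    dv_cs = abs(state.dv_cs())
    dv_color = abs(state.dv_color_effective(params.tau_color)) if include_color else 0.0
    urgency = 1.0 - params.tau ** t
    logit = (params.alpha_gather + params.beta_dCs * dv_cs
             + params.beta_dcolor * dv_color + params.beta_time * urgency)
    return float(expit(logit))


def p_look_right(state: BeliefState, params: AgentParams,
                 include_color: bool = True) -> float:
    """Probability that the next fixation lands on the right ring."""
    dv_cs = state.dv_cs()
    dv_color = state.dv_color_effective(params.tau_color) if include_color else 0.0
    if state.last_side is None:
        stay = 0.0
    else:
        stay = 1.0 if state.last_side == "right" else -1.0
    logit = (params.alpha_look_right + params.beta_look_color * dv_color
             + params.beta_look_Cs * dv_cs + params.beta_look_stay * stay)
    return float(expit(logit))


def p_choose_right(state: BeliefState, params: AgentParams) -> float:
    """Softmax choice on the combined value difference.

    Color-only trials use the learned color values directly (there is no
    perceptual sampling to pace retrieval against); combined trials use the
    retrieval-scaled effective value at the stop step.
    """
    trial_type = state.current_trial.trial_type
    if trial_type == "color_only":
        dv = params.omega_color * state.dv_color_learned()
    elif trial_type == "cs_only":
        dv = state.dv_cs()
    else:
        dv = state.dv_cs() + params.omega_color * state.dv_color_effective(
            params.tau_color)
    return float(expit(params.beta_choose * dv))


# ---------------------------------------------------------------------------
# learning
# ---------------------------------------------------------------------------

def td_update(state: BeliefState, chosen: Stimulus, reward: int,
              params: AgentParams, use_true_cs_value: bool = False) -> BeliefState:
    """Temporal-difference update of the chosen stimulus's color value.

    delta = r - (V_chosen_Cs + V_chosen_color); the learning rate
    1/(epsilon + n/2) decays with the number of outcomes n observed for the
    color (including this one -- the first update uses 1/(epsilon + 0.5)),
    halved because each outcome is only half attributable to the color.
    ``V_chosen_Cs`` is the agent's believed C value at choice time by
    default, or the true-up-count value with ``use_true_cs_value``.
    """
    if not chosen.has_color:
        return state
    cid = chosen.color_id
    trial_type = state.current_trial.trial_type
    if trial_type == "color_only":
        v_cs = 0.0
    elif use_true_cs_value:
        onehot = np.array([1.0 if n == chosen.up_count else 0.0
                           for n in state.config.up_levels])
        v_cs = cs_value(onehot, trial_type, state.config.up_levels,
                        config=state.config)
    else:
        v_cs = state.cs_side_value(chosen.side)
    v_color = state.v_color_learned.get(cid, 0.0)
    delta = reward - (v_cs + v_color)
    n = state.n_color_outcomes.get(cid, 0) + 1
    state.n_color_outcomes[cid] = n
    eta = 1.0 / (params.epsilon + 0.5 * n)
    state.v_color_learned[cid] = v_color + eta * delta
    return state


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def select_c_to_fixate(state: BeliefState, side: Side,
                       rng: np.random.Generator) -> int:
    """Fixate a uniformly drawn not-yet-fixated C on ``side``.

    Updates the belief state (fixated set, up/down counts, last side, step)
    according to the C's true orientation.
    """
    available = state.unfixated(side)
    if not available:
        raise ExhaustionError(f"all Cs on {side} already fixated")
    c_index = int(available[rng.integers(len(available))])
    state.apply_fixation(side, c_index)
    return c_index


@dataclass(frozen=True)
class TrialRecord:
    """One simulated (or observed) trial trajectory."""

    trial: int
    trial_type: str
    sides: tuple[Side, ...]
    c_indices: tuple[int, ...]
    c_orientations: tuple[bool, ...]
    choice: Side
    reward: int
    v_color_left: float  # learned color values at trial onset
    v_color_right: float

    @property
    def n_fixations(self) -> int:
        return len(self.sides)

    @property
    def rt_proxy(self) -> int:
        """Steps to choice: the decision index at which the agent stopped."""
        return len(self.sides) + 1


def simulate_trial(trial: Trial, state: BeliefState, params: AgentParams,
                   rng: np.random.Generator,
                   max_steps: int = DEFAULT_MAX_STEPS,
                   use_true_cs_value: bool = False) -> TrialRecord:
    """Run one trial of the generative loop and apply the learning update."""
    state.begin_trial(trial)
    v_left = state.color_value("left")
    v_right = state.color_value("right")
    sides: list[Side] = []
    c_indices: list[int] = []
    orientations: list[bool] = []
    if trial.trial_type != "color_only":
        while state.step < max_steps and not state.both_exhausted():
            if rng.random() >= p_continue_gathering(state, params):
                break
            side: Side = "right" if rng.random() < p_look_right(state, params) \
                else "left"
            if state.side_exhausted(side):
                side = "left" if side == "right" else "right"
            c_index = select_c_to_fixate(state, side, rng)
            sides.append(side)
            c_indices.append(c_index)
            orientations.append(bool(trial.stimulus(side).orientations[c_index]))
    choice: Side = "right" if rng.random() < p_choose_right(state, params) \
        else "left"
    chosen = trial.stimulus(choice)
    reward = draw_reward(true_reward_prob(trial.trial_type, chosen, state.config),
                         rng)
    td_update(state, chosen, reward, params, use_true_cs_value=use_true_cs_value)
    return TrialRecord(
        trial=trial.trial, trial_type=trial.trial_type, sides=tuple(sides),
        c_indices=tuple(c_indices), c_orientations=tuple(orientations),
        choice=choice, reward=reward,
        v_color_left=v_left, v_color_right=v_right,
    )


def simulate_participant(schedule: TaskSchedule, params: AgentParams, seed: int,
                         max_steps: int = DEFAULT_MAX_STEPS,
                         use_true_cs_value: bool = False) -> list[TrialRecord]:
    """Simulate a full session, carrying learned color values across trials."""
    rng = np.random.default_rng(seed)
    state = BeliefState(config=schedule.config)
    return [
        simulate_trial(trial, state, params, rng, max_steps=max_steps,
                       use_true_cs_value=use_true_cs_value)
        for trial in schedule
    ]
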