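"""Log-likelihood of fixation side-sequences, stopping points and choices.

The likelihood factorizes over decision events: for every completed fixation
a gather factor (continue) and a look factor (side), one stop factor at the
observed stopping point, and one choice factor per trial.  Which specific C
within a side was fixated is uniform over the not-yet-fixated Cs and
parameter-free, so it is omitted as a constant.  Forced events carry no
factor: the stop when the fixation cap or both rings are exhausted, and the
look when one ring is exhausted.

Two equivalent implementations are provided: :func:`trial_loglik` replays a
single trial through the :class:`~gazetrade.agent.BeliefState` machinery
(the readable reference, also used by the enumeration tests), while
:func:`dataset_loglik_many` evaluates a whole session for a matrix of
parameter vectors at once on a precompiled event table -- the inner loop of
the hierarchical fitter.  Probabilities are floored at 1e-12 before taking
logs so that importance weights stay finite under extreme proposals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import log_expit

from .agent import (
    DEFAULT_MAX_STEPS,
    PARAM_NAMES,
    AgentParams,
    BeliefState,
    TrialRecord,
    p_choose_right,
    p_continue_gathering,
    p_look_right,
    td_update,
)
from .task import DataError, TaskSchedule, Trial

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "ObservedTrial",
    "ParticipantData",
    "trial_loglik",
    "dataset_loglik",
    "dataset_loglik_many",
    "PROB_FLOOR",
]

PROB_FLOOR = 1e-12
_LOG_FLOOR = float(np.log(PROB_FLOOR))

_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}


@dataclass(frozen=True)
class ModelSpec:
    """Which decisions may consult the learned color values.

    The full model uses color in both the gather-versus-choose decision and
    the sampling-location decision; each reduced variant drops one, removing
    the corresponding weight from the parameter set.
    """

    name: str = "full"
    include_color_in_gather: bool = True
    include_color_in_look: bool = True

    @property
    def active_params(self) -> tuple[str, ...]:
        dropped = set()
        if not self.include_color_in_gather:
            dropped.add("beta_dcolor")
        if not self.include_color_in_look:
            dropped.add("beta_look_color")
        return tuple(n for n in PARAM_NAMES if n not in dropped)

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            return MODEL_SPECS[name]
        except KeyError:
            raise DataError(f"unknown model spec {name!r}; "
                            f"choose from {sorted(MODEL_SPECS)}")


MODEL_SPECS = {
    "full": ModelSpec("full", True, True),
    "no-color-gather": ModelSpec("no-color-gather", False, True),
    "no-color-look": ModelSpec("no-color-look", True, False),
}


@dataclass(frozen=True)
class ObservedTrial:
    """One trial's observables: fixation sequence, choice and outcome."""

    trial: Trial
    sides: tuple[str, ...]
    c_indices: tuple[int, ...]
    choice: str
    reward: int

    def orientation(self, k: int) -> bool:
        stim = self.trial.stimulus(self.sides[k])
        idx = self.c_indices[k]
        if stim.orientations is None or not 0 <= idx < len(stim.orientations):
            raise DataError(f"fixation references unknown C {idx}")
        return bool(stim.orientations[idx])


@dataclass
class ParticipantData:
    """A session's observed trials tied to their schedule."""

    schedule: TaskSchedule
    trials: list[ObservedTrial]
    max_steps: int = DEFAULT_MAX_STEPS
    _compiled: Optional["_CompiledSession"] = field(default=None, repr=False,
                                                   compare=False)

    @classmethod
    def from_records(cls, schedule: TaskSchedule, records: Sequence[TrialRecord],
                     max_steps: int = DEFAULT_MAX_STEPS) -> "ParticipantData":
        by_index = {t.trial: t for t in schedule}
        obs = [
            ObservedTrial(trial=by_index[r.trial], sides=r.sides,
                          c_indices=r.c_indices, choice=r.choice,
                          reward=r.reward)
            for r in records
        ]
        return cls(schedule=schedule, trials=obs, max_steps=max_steps)

    @classmethod
    def from_frames(cls, schedule: TaskSchedule, trial_frame, fixation_frame,
                    max_steps: int = DEFAULT_MAX_STEPS) -> "ParticipantData":
        """Assemble from the trial CSV + long fixation CSV representation."""
        by_index = {t.trial: t for t in schedule}
        fix_by_trial: dict[int, list] = {}
        if fixation_frame is not None and len(fixation_frame):
            for trial_idx, grp in fixation_frame.groupby("trial"):
                grp = grp.sort_values("fix_index")
                fix_by_trial[int(trial_idx)] = list(
                    zip(grp["side"].astype(str), grp["c_index"].astype(int)))
        obs = []
        for _, row in trial_frame.iterrows():
            idx = int(row["trial"])
            fixes = fix_by_trial.get(idx, [])
            obs.append(ObservedTrial(
                trial=by_index[idx],
                sides=tuple(s for s, _ in fixes),
                c_indices=tuple(c for _, c in fixes),
                choice=str(row["choice"]),
                reward=int(row["reward"]),
            ))
        return cls(schedule=schedule, trials=obs, max_steps=max_steps)

    @property
    def compiled(self) -> "_CompiledSession":
        if self._compiled is None:
            self._compiled = _compile(self)
        return self._compiled

    @property
    def n_decisions(self) -> int:
        """Count of modeled decision events (gather + look + choice)."""
        c = self.compiled
        return len(c.g_t) + len(c.l_t) + len(c.c_t)


# ---------------------------------------------------------------------------
# reference implementation: single trial, single parameter vector
# ---------------------------------------------------------------------------

def _log_floor(p: float) -> float:
    return float(np.log(max(p, PROB_FLOOR)))


def trial_loglik(trial_data: ObservedTrial, state: BeliefState,
                 params: AgentParams, spec: ModelSpec = MODEL_SPECS["full"],
                 max_steps: int = DEFAULT_MAX_STEPS,
                 ) -> tuple[float, BeliefState]:
    """Log-probability of one trial's decisions; advances the belief state."""
    trial = trial_data.trial
    state.begin_trial(trial)
    ll = 0.0
    if trial.trial_type != "color_only":
        for k, side in enumerate(trial_data.sides):
            if state.step >= max_steps or state.both_exhausted():
                raise DataError("more fixations than the model permits")
            p_cont = p_continue_gathering(
                state, params, include_color=spec.include_color_in_gather)
            ll += _log_floor(p_cont)
            if not (state.side_exhausted("left") or state.side_exhausted("right")):
                p_r = p_look_right(
                    state, params, include_color=spec.include_color_in_look)
                ll += _log_floor(p_r if side == "right" else 1.0 - p_r)
            state.apply_fixation(side, trial_data.c_indices[k])
        if state.step < max_steps and not state.both_exhausted():
            p_cont = p_continue_gathering(
                state, params, include_color=spec.include_color_in_gather)
            ll += _log_floor(1.0 - p_cont)
    p_r = p_choose_right(state, params)
    ll += _log_floor(p_r if trial_data.choice == "right" else 1.0 - p_r)
    td_update(state, trial.stimulus(trial_data.choice), trial_data.reward, params)
    return ll, state


def fold_trial_logliks(data: ParticipantData, params: AgentParams,
                       spec: ModelSpec = MODEL_SPECS["full"]) -> float:
    """Sum trial logliks in order with persistent learning (reference path)."""
    state = BeliefState(config=data.schedule.config)
    total = 0.0
    for td in data.trials:
        ll, state = trial_loglik(td, state, params, spec,
                                 max_steps=data.max_steps)
        total += ll
    return total


# ---------------------------------------------------------------------------
# compiled event-table implementation
# ---------------------------------------------------------------------------

@dataclass
class _CompiledSession:
    """Parameter-free event tables for fast many-sample evaluation."""

    n_colors: int
    # per trial
    color_left: np.ndarray   # int, -1 if absent
    color_right: np.ndarray
    chosen_color: np.ndarray  # -1 when the chosen stimulus has no color
    reward: np.ndarray
    vcsb_chosen: np.ndarray  # believed C value of the chosen side at stop
    n_outcome: np.ndarray    # outcome count incl. current, per chosen color
    # gather events
    g_trial: np.ndarray
    g_t: np.ndarray
    g_dvcs: np.ndarray
    g_sign: np.ndarray       # +1 continue, -1 stop
    g_hascolor: np.ndarray   # 1.0 on combined trials
    # look events
    l_trial: np.ndarray
    l_t: np.ndarray
    l_dvcs: np.ndarray
    l_sign: np.ndarray       # +1 looked right, -1 looked left
    l_stay: np.ndarray
    l_hascolor: np.ndarray
    # choice events
    c_trial: np.ndarray
    c_t: np.ndarray
    c_dvcs: np.ndarray
    c_sign: np.ndarray       # +1 chose right
    c_colorfactor: np.ndarray  # 0 cs_only, 1 color_only (learned), 2 combined


def _compile(data: ParticipantData) -> _CompiledSession:
    cfg = data.schedule.config
    state = BeliefState(config=cfg)
    T = len(data.trials)
    color_left = np.full(T, -1, dtype=int)
    color_right = np.full(T, -1, dtype=int)
    chosen_color = np.full(T, -1, dtype=int)
    reward = np.zeros(T)
    vcsb = np.zeros(T)
    n_outcome = np.zeros(T, dtype=int)
    counts: dict[int, int] = {}
    g_rows, l_rows, c_rows = [], [], []
    for i, td in enumerate(data.trials):
        trial = td.trial
        state.begin_trial(trial)
        for side in ("left", "right"):
            stim = trial.stimulus(side)
            if stim.has_color:
                (color_left if side == "left" else color_right)[i] = stim.color_id
        is_combined = trial.trial_type == "combined"
        if trial.trial_type != "color_only":
            for k, side in enumerate(td.sides):
                if state.step >= data.max_steps or state.both_exhausted():
                    raise DataError("more fixations than the model permits")
                g_rows.append((i, state.step + 1, state.dv_cs(), +1.0,
                               float(is_combined)))
                if not (state.side_exhausted("left")
                        or state.side_exhausted("right")):
                    l_rows.append((i, state.step + 1, state.dv_cs(),
                                   1.0 if side == "right" else -1.0,
                                   0.0 if state.last_side is None
                                   else (1.0 if state.last_side == "right"
                                         else -1.0),
                                   float(is_combined)))
                state.apply_fixation(side, td.c_indices[k])
            if state.step < data.max_steps and not state.both_exhausted():
                g_rows.append((i, state.step + 1, state.dv_cs(), -1.0,
                               float(is_combined)))
        ttype = {"cs_only": 0.0, "color_only": 1.0, "combined": 2.0}
        c_rows.append((i, state.step + 1,
                       0.0 if trial.trial_type == "color_only" else state.dv_cs(),
                       1.0 if td.choice == "right" else -1.0,
                       ttype[trial.trial_type]))
        reward[i] = td.reward
        chosen = trial.stimulus(td.choice)
        if chosen.has_color:
            chosen_color[i] = chosen.color_id
            counts[chosen.color_id] = counts.get(chosen.color_id, 0) + 1
            n_outcome[i] = counts[chosen.color_id]
            vcsb[i] = (state.cs_side_value(td.choice)
                       if trial.trial_type == "combined" else 0.0)

    def cols(rows, n):
        if not rows:
            return [np.zeros(0) for _ in range(n)]
        return [np.asarray(c) for c in zip(*rows)]

    g = cols(g_rows, 5)
    l = cols(l_rows, 6)
    c = cols(c_rows, 5)
    n_colors = int(max(color_left.max(initial=-1),
                       color_right.max(initial=-1))) + 1
    return _CompiledSession(
        n_colors=max(n_colors, 1),
        color_left=color_left, color_right=color_right,
        chosen_color=chosen_color, reward=reward, vcsb_chosen=vcsb,
        n_outcome=n_outcome,
        g_trial=g[0].astype(int), g_t=g[1].astype(int), g_dvcs=g[2],
        g_sign=g[3], g_hascolor=g[4],
        l_trial=l[0].astype(int), l_t=l[1].astype(int), l_dvcs=l[2],
        l_sign=l[3], l_stay=l[4], l_hascolor=l[5],
        c_trial=c[0].astype(int), c_t=c[1].astype(int), c_dvcs=c[2],
        c_sign=c[3], c_colorfactor=c[4],
    )


def _color_value_paths(comp: _CompiledSession, eps: np.ndarray) -> np.ndarray:
    """Learned right-minus-left color value per trial, per sample: (T, S)."""
    S = len(eps)
    V = np.zeros((comp.n_colors, S))
    T = len(comp.reward)
    dvl = np.zeros((T, S))
    for i in range(T):
        cl, cr = comp.color_left[i], comp.color_right[i]
        vl = V[cl] if cl >= 0 else 0.0
        vr = V[cr] if cr >= 0 else 0.0
        dvl[i] = vr - vl
        cc = comp.chosen_color[i]
        if cc >= 0:
            delta = comp.reward[i] - comp.vcsb_chosen[i] - V[cc]
            V[cc] += delta / (eps + 0.5 * comp.n_outcome[i])
    return dvl


def dataset_loglik_many(data: ParticipantData, theta: np.ndarray,
                        spec: ModelSpec = MODEL_SPECS["full"],
                        chunk: int = 256) -> np.ndarray:
    """Session log-likelihood for each row of ``theta`` (S, 13) at once."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    out = np.empty(len(theta))
    for lo in range(0, len(theta), chunk):
        out[lo:lo + chunk] = _loglik_chunk(data.compiled, theta[lo:lo + chunk],
                                           spec)
    return out


def _powers(base: np.ndarray, max_t: int) -> np.ndarray:
    """base[s] ** t for t = 1..max_t, shape (max_t + 1, S); row 0 is t=1."""
    S = len(base)
    if max_t < 1:
        return np.zeros((1, S))
    pw = np.empty((max_t, S))
    pw[0] = base
    for t in range(1, max_t):
        pw[t] = pw[t - 1] * base
    return pw


def _loglik_chunk(comp: _CompiledSession, theta: np.ndarray,
                  spec: ModelSpec) -> np.ndarray:
    p = {name: theta[:, _IDX[name]] for name in PARAM_NAMES}
    dvl = _color_value_paths(comp, p["epsilon"])
    max_t = int(max(comp.g_t.max(initial=1), comp.l_t.max(initial=1),
                    comp.c_t.max(initial=1)))
    tau_pow = _powers(p["tau"], max_t)
    tc_pow = _powers(p["tau_color"], max_t)
    ll = np.zeros(theta.shape[0])

    if len(comp.g_t):
        retr = 1.0 - tc_pow[comp.g_t - 1]
        if spec.include_color_in_gather:
            dvc = np.abs(dvl[comp.g_trial] * retr) * comp.g_hascolor[:, None]
            color_term = p["beta_dcolor"] * dvc
        else:
            color_term = 0.0
        logit = (p["alpha_gather"]
                 + p["beta_dCs"] * np.abs(comp.g_dvcs)[:, None]
                 + color_term
                 + p["beta_time"] * (1.0 - tau_pow[comp.g_t - 1]))
        ll += np.maximum(log_expit(comp.g_sign[:, None] * logit),
                         _LOG_FLOOR).sum(axis=0)

    if len(comp.l_t):
        if spec.include_color_in_look:
            retr = 1.0 - tc_pow[comp.l_t - 1]
            dvc = dvl[comp.l_trial] * retr * comp.l_hascolor[:, None]
            color_term = p["beta_look_color"] * dvc
        else:
            color_term = 0.0
        logit = (p["alpha_look_right"] + color_term
                 + p["beta_look_Cs"] * comp.l_dvcs[:, None]
                 + p["beta_look_stay"] * comp.l_stay[:, None])
        ll += np.maximum(log_expit(comp.l_sign[:, None] * logit),
                         _LOG_FLOOR).sum(axis=0)

    # choice: retrieval factor is (1 - tau_color^t) on combined trials, 1 on
    # color-only trials (learned value used directly), 0 on Cs-only trials
    factor = np.where(comp.c_colorfactor[:, None] == 2.0,
                      1.0 - tc_pow[comp.c_t - 1],
                      (comp.c_colorfactor == 1.0)[:, None].astype(float))
    dv = comp.c_dvcs[:, None] + p["omega_color"] * dvl[comp.c_trial] * factor
    logit = p["beta_choose"] * dv
    ll += np.maximum(log_expit(comp.c_sign[:, None] * logit),
                     _LOG_FLOOR).sum(axis=0)
    return ll


def dataset_loglik(data: ParticipantData, params: AgentParams,
                   spec: ModelSpec = MODEL_SPECS["full"]) -> float:
    """Session log-likelihood for a single parameter vector."""
    return float(dataset_loglik_many(data, params.to_array()[None, :], spec)[0])
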