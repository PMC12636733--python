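"""Synthetic cohorts with known ground truth.

Generates everything the downstream stages consume: per-participant task
schedules (counterbalanced color assignments), agent-simulated fixation
sequences, choices and rewards, and pixel-level fixation reports placed at
the Landolt-C interest areas -- so the eye-parsing stage, the likelihood,
the hierarchical fitter and the regression analyses can all be exercised
end to end without any external data.

The default generating group distribution encodes the qualitative regime
the task is designed around: a positive baseline tendency to gather
(alpha_gather ~ 3), negative evidence and urgency weights so that larger
value differences and elapsed time both promote stopping (beta_dCs ~ -1,
beta_dcolor ~ -1.5, beta_time ~ -4 with tau ~ 0.9), value-guided and
perseverative looking, a softmax choice with partial color weighting
(beta_choose ~ 5, omega_color ~ 0.5), fast color retrieval
(tau_color ~ 0.23, i.e. ~95% of the learned value by the second fixation)
and a learning-rate offset epsilon ~ 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agent import (
    DEFAULT_MAX_STEPS,
    AgentParams,
    TrialRecord,
    simulate_participant,
)
from .eye import FixationRecord, InterestArea, InterestAreaMap
from .fitting import (
    GroupHyperparams,
    _constrain_matrix,
    _full_theta,
    _sample_unconstrained,
    iis_fit,
)
from .likelihood import MODEL_SPECS, ModelSpec, ParticipantData
from .task import ConfigurationError, TaskConfig, TaskSchedule, generate_task

__all__ = [
    "ScreenGeometry",
    "CohortSpec",
    "ParticipantSim",
    "SyntheticCohort",
    "default_generating_hyperparams",
    "generate_cohort",
    "recovery_harness",
    "records_to_frames",
]


def default_generating_hyperparams() -> GroupHyperparams:
    """Group distribution (unconstrained space) used to draw participants."""
    from scipy.special import ndtri
    mu = {
        "alpha_gather": 3.0,
        "beta_dCs": -1.0,
        "beta_dcolor": -1.5,
        "beta_time": -4.0,
        "tau": float(ndtri(0.9)),
        "alpha_look_right": 0.0,
        "beta_look_color": 1.5,
        "beta_look_Cs": 1.0,
        "beta_look_stay": 1.0,
        "beta_choose": 5.0,
        "omega_color": 0.0,            # probit -> omega ~ 0.5
        "tau_color": float(ndtri(0.2324)),
        "epsilon": 0.0,                # log -> epsilon ~ 1
    }
    sd = {name: 0.5 for name in mu}
    sd.update({"tau": 0.3, "tau_color": 0.3, "alpha_look_right": 0.3,
               "epsilon": 0.3, "beta_choose": 1.0})
    return GroupHyperparams(mu=mu, sd=sd)


@dataclass(frozen=True)
class ScreenGeometry:
    """Pixel layout of the two C rings (origin top-left)."""

    screen_width: int = 1920
    screen_height: int = 1080
    left_center: tuple[float, float] = (560.0, 540.0)
    right_center: tuple[float, float] = (1360.0, 540.0)
    ring_radius: float = 150.0
    n_cs: int = 12

    @property
    def acceptance_radius(self) -> float:
        """Half the center-to-center spacing of adjacent Cs."""
        return self.ring_radius * float(np.sin(np.pi / self.n_cs))

    def c_center(self, side: str, c_index: int) -> tuple[float, float]:
        cx, cy = self.left_center if side == "left" else self.right_center
        angle = 2.0 * np.pi * c_index / self.n_cs - np.pi / 2.0
        return (cx + self.ring_radius * np.cos(angle),
                cy + self.ring_radius * np.sin(angle))

    def interest_area_map(self, schedule: TaskSchedule) -> InterestAreaMap:
        areas = []
        for trial in schedule:
            for side in ("left", "right"):
                if not trial.stimulus(side).has_cs:
                    continue
                for i in range(self.n_cs):
                    x, y = self.c_center(side, i)
                    areas.append(InterestArea(
                        trial=trial.trial, side=side, c_index=i,
                        x=x, y=y, radius=self.acceptance_radius))
        return InterestAreaMap(areas=areas)


@dataclass(frozen=True)
class CohortSpec:
    """Conditions of a simulated study."""

    n_participants: int = 30
    config: TaskConfig = field(default_factory=TaskConfig)
    hyper: GroupHyperparams = field(
        default_factory=default_generating_hyperparams)
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    seed: int = 0
    max_steps: int = DEFAULT_MAX_STEPS
    jitter_sd_frac: float = 0.25   # fixation jitter sd as fraction of radius
    jitter_clip_frac: float = 0.95
    fixation_duration_ms: float = 200.0
    fixation_interval_ms: float = 250.0
    trial_gap_ms: float = 1000.0
    degraded_validity_fraction: float = 0.0  # participants pushed below 75%

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be nonnegative")
        if self.geometry.n_cs != self.config.n_cs_per_stimulus:
            raise ConfigurationError("geometry/config C counts differ")


@dataclass
class ParticipantSim:
    pid: int
    params: AgentParams
    schedule: TaskSchedule
    records: list[TrialRecord]
    fixations: list[FixationRecord]
    validity: float

    def data(self, max_steps: int = DEFAULT_MAX_STEPS) -> ParticipantData:
        return ParticipantData.from_records(self.schedule, self.records,
                                            max_steps=max_steps)

    def fixation_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.__dict__ for f in self.fixations],
                            columns=["participant", "trial", "t_start",
                                     "duration", "x", "y"])


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    participants: list[ParticipantSim]

    def __len__(self) -> int:
        return len(self.participants)

    def data_list(self) -> list[ParticipantData]:
        return [p.data(max_steps=self.spec.max_steps)
                for p in self.participants]

    def true_params_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.params.to_dict() for p in self.participants])

    def validity_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant": [p.pid for p in self.participants],
            "validity": [p.validity for p in self.participants],
        })

    def to_dir(self, path) -> None:
        """Write the file formats the parsing/analysis stages consume."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for p in self.participants:
            d = out / f"participant_{p.pid:03d}"
            d.mkdir(exist_ok=True)
            p.schedule.to_csv(d / "schedule.csv")
            trials, fixes = records_to_frames(p.records)
            trials.to_csv(d / "trials.csv", index=False)
            fixes.to_csv(d / "fixations.csv", index=False)
            p.fixation_frame().to_csv(d / "fixation_report.tsv", sep="\t",
                                      index=False)
            self.spec.geometry.interest_area_map(p.schedule).to_csv(
                d / "interest_areas.csv")
            (d / "true_params.json").write_text(json.dumps(p.params.to_dict()))
        self.validity_frame().to_csv(out / "validity.csv", index=False)


def records_to_frames(records: Sequence[TrialRecord]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial-level and long-format fixation tables for a session."""
    trial_rows, fix_rows = [], []
    for r in records:
        trial_rows.append({
            "trial": r.trial, "trial_type": r.trial_type, "choice": r.choice,
            "reward": r.reward, "n_fixations": r.n_fixations,
            "rt_proxy": r.rt_proxy, "v_color_left": r.v_color_left,
            "v_color_right": r.v_color_right,
        })
        for k, (side, ci, ori) in enumerate(
                zip(r.sides, r.c_indices, r.c_orientations)):
            fix_rows.append({"trial": r.trial, "fix_index": k, "side": side,
                             "c_index": ci, "up": int(ori)})
    return (pd.DataFrame(trial_rows,
                         columns=["trial", "trial_type", "choice", "reward",
                                  "n_fixations", "rt_proxy", "v_color_left",
                                  "v_color_right"]),
            pd.DataFrame(fix_rows, columns=["trial", "fix_index", "side",
                                            "c_index", "up"]))


def _jittered(center: tuple[float, float], radius: float, sd: float,
              clip: float, rng: np.random.Generator) -> tuple[float, float]:
    for _ in range(50):
        dx, dy = rng.normal(0.0, sd, size=2)
        # 0.01 px report precision; keep the rounded point inside the radius
        x = round(float(center[0] + dx), 2)
        y = round(float(center[1] + dy), 2)
        if np.hypot(x - center[0], y - center[1]) < clip * radius:
            return (x, y)
    return (round(float(center[0]), 2), round(float(center[1]), 2))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw participants from the group distribution and simulate them."""
    root = np.random.SeedSequence(spec.seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    n = spec.n_participants
    participants: list[ParticipantSim] = []
    if n:
        from .agent import PARAM_NAMES
        x = _sample_unconstrained(spec.hyper, n, param_rng, PARAM_NAMES)
        theta = _full_theta(_constrain_matrix(x, PARAM_NAMES), PARAM_NAMES)
    n_degraded = int(round(spec.degraded_validity_fraction * n))
    for j in range(n):
        child = np.random.SeedSequence([spec.seed, 1 + j])
        task_seed, sim_seed, eye_seed = [
            int(s.generate_state(1)[0] % (2 ** 31)) for s in child.spawn(3)]
        params = AgentParams.from_array(theta[j])
        schedule = generate_task(spec.config, seed=task_seed)
        records = simulate_participant(schedule, params, seed=sim_seed,
                                       max_steps=spec.max_steps)
        eye_rng = np.random.default_rng(eye_seed)
        fixations = _emit_fixations(j, records, spec, eye_rng)
        validity = 0.5 if j < n_degraded else 1.0
        participants.append(ParticipantSim(
            pid=j, params=params, schedule=schedule, records=records,
            fixations=fixations, validity=validity))
    return SyntheticCohort(spec=spec, participants=participants)


def _emit_fixations(pid: int, records: Sequence[TrialRecord],
                    spec: CohortSpec, rng: np.random.Generator
                    ) -> list[FixationRecord]:
    geom = spec.geometry
    sd = spec.jitter_sd_frac * geom.acceptance_radius
    out: list[FixationRecord] = []
    t = 0.0
    for r in records:
        for k, (side, ci) in enumerate(zip(r.sides, r.c_indices)):
            x, y = _jittered(geom.c_center(side, ci), geom.acceptance_radius,
                             sd, spec.jitter_clip_frac, rng)
            out.append(FixationRecord(
                participant=pid, trial=r.trial,
                t_start=t + k * spec.fixation_interval_ms,
                duration=spec.fixation_duration_ms, x=x, y=y))
        t += len(r.sides) * spec.fixation_interval_ms + spec.trial_gap_ms
    return out


def recovery_harness(spec: CohortSpec,
                     model: ModelSpec = MODEL_SPECS["full"],
                     n_samples: int = 2000, max_iters: int = 50,
                     tol: float = 1e-2, fit_seed: int = 1,
                     verbose: bool = False) -> dict:
    """Generate a cohort, fit it, and tabulate parameter recovery.

    Returns the cohort, the fit, and a table with one row per free
    parameter: generating group mean/sd, recovered group mean/sd, and the
    across-participant correlation between true and posterior-mean values
    (constrained space).
    """
    cohort = generate_cohort(spec)
    fit = iis_fit(cohort.data_list(), model, n_samples=n_samples,
                  max_iters=max_iters, tol=tol, seed=fit_seed,
                  verbose=verbose)
    true_con = cohort.true_params_frame()
    rows = []
    for name in fit.param_names:
        true_vals = true_con[name].to_numpy()
        rec_vals = fit.posterior_means[name].to_numpy()
        if np.std(true_vals) > 0 and np.std(rec_vals) > 0:
            r = float(np.corrcoef(true_vals, rec_vals)[0, 1])
        else:
            r = np.nan
        rows.append({
            "parameter": name,
            "true_group_mu": spec.hyper.mu[name],
            "true_group_sd": spec.hyper.sd[name],
            "recovered_group_mu": fit.hyper.mu[name],
            "recovered_group_sd": fit.hyper.sd[name],
            "recovery_r": r,
            "mean_true": float(true_vals.mean()),
            "mean_recovered": float(rec_vals.mean()),
        })
    return {"cohort": cohort, "fit": fit, "table": pd.DataFrame(rows)}
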