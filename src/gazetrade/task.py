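"""Two-armed bandit task structure: stimuli, schedules, and the reward process.

Each stimulus combines a colored circle, whose reward probability must be
learned by trial and error, and a ring of 12 Landolt Cs, whose reward
probability is instructed to scale linearly with the number of upward-facing
Cs (3, 6 or 9 out of 12).  The two components contribute additively and with
equal weight to the probability that choosing the stimulus pays out.

Blocks 1 and 2 each introduce three new colors (reward probabilities 0, 0.5
and 1) and interleave combined trials with single-component trials; block 3
re-uses all six colors in combined trials only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TrialType = str  # "combined" | "cs_only" | "color_only"
Side = str  # "left" | "right"

TRIAL_TYPES = ("combined", "cs_only", "color_only")
SIDES = ("left", "right")

#: reward-probability contribution of each up-count level (linear scaling)
CS_PROB = {3: 0.0, 6: 0.5, 9: 1.0}


class ConfigurationError(ValueError):
    """Raised when a task configuration violates its invariants."""


class DataError(ValueError):
    """Raised when observed/simulated data are inconsistent with the task."""


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the task.

    Defaults reproduce the experiment: 12 Cs per ring with 3/6/9 facing up,
    two color sets with reward probabilities {0, 0.5, 1}, block compositions
    (combined, cs_only, color_only) of 36/18/18 in blocks 1-2 and 162/0/0 in
    block 3, and a 4 s choice deadline.
    """

    n_cs_per_stimulus: int = 12
    up_levels: tuple[int, ...] = (3, 6, 9)
    color_probs_per_block: tuple[tuple[float, ...], ...] = (
        (0.0, 0.5, 1.0),
        (0.0, 0.5, 1.0),
    )
    block_composition: tuple[tuple[int, int, int], ...] = (
        (36, 18, 18),
        (36, 18, 18),
        (162, 0, 0),
    )
    choice_deadline: float = 4.0
    reward_unit: float = 1.0
    allow_identical_pairs: bool = False
    include_practice: bool = False
    n_practice_per_type: int = 10

    def __post_init__(self) -> None:
        if self.n_cs_per_stimulus <= 0:
            raise ConfigurationError("n_cs_per_stimulus must be positive")
        if not self.up_levels:
            raise ConfigurationError("up_levels must be nonempty")
        for lvl in self.up_levels:
            if not 0 <= lvl <= self.n_cs_per_stimulus:
                raise ConfigurationError(
                    f"up level {lvl} outside [0, {self.n_cs_per_stimulus}]"
                )
        for probs in self.color_probs_per_block:
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"color probability {p} outside [0, 1]")
        for counts in self.block_composition:
            if len(counts) != 3 or any(c < 0 for c in counts):
                raise ConfigurationError(
                    "block_composition entries must be 3 nonnegative counts"
                )

    @property
    def n_colors(self) -> int:
        return sum(len(p) for p in self.color_probs_per_block)

    def cs_prob(self, up_count: int) -> float:
        """Instructed reward probability of a ring with ``up_count`` up Cs."""
        lo, hi = min(self.up_levels), max(self.up_levels)
        if hi == lo:
            return 0.5
        return (up_count - lo) / (hi - lo)

    def to_json(self) -> str:
        d = {
            k: getattr(self, k)
            for k in (
                "n_cs_per_stimulus",
                "up_levels",
                "color_probs_per_block",
                "block_composition",
                "choice_deadline",
                "reward_unit",
                "allow_identical_pairs",
                "include_practice",
                "n_practice_per_type",
            )
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "TaskConfig":
        d = json.loads(s)
        d["up_levels"] = tuple(d["up_levels"])
        d["color_probs_per_block"] = tuple(
            tuple(p) for p in d["color_probs_per_block"]
        )
        d["block_composition"] = tuple(tuple(c) for c in d["block_composition"])
        return cls(**d)


@dataclass(frozen=True)
class Stimulus:
    """One choice option: a colored circle, a Landolt-C ring, or both."""

    side: Side
    color_id: Optional[int] = None
    p_color: Optional[float] = None
    up_count: Optional[int] = None
    orientations: Optional[tuple[bool, ...]] = None  # True = gap up

    def __post_init__(self) -> None:
        if (self.color_id is None) != (self.p_color is None):
            raise DataError("color_id and p_color must be given together")
        if (self.up_count is None) != (self.orientations is None):
            raise DataError("up_count and orientations must be given together")
        if self.orientations is not None and sum(self.orientations) != self.up_count:
            raise DataError("orientations do not sum to up_count")

    @property
    def has_color(self) -> bool:
        return self.color_id is not None

    @property
    def has_cs(self) -> bool:
        return self.up_count is not None


@dataclass(frozen=True)
class Trial:
    block: int
    trial: int
    trial_type: TrialType
    left: Stimulus
    right: Stimulus
    is_practice: bool = False

    def stimulus(self, side: Side) -> Stimulus:
        return self.left if side == "left" else self.right


@dataclass
class TaskSchedule:
    """Ordered trial list for one participant."""

    config: TaskConfig
    trials: list[Trial] = field(default_factory=list)
    color_probs: dict[int, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            row: dict = {
                "block": t.block,
                "trial": t.trial,
                "trial_type": t.trial_type,
                "is_practice": int(t.is_practice),
            }
            for side in SIDES:
                s = t.stimulus(side)
                row[f"{side}_color_id"] = -1 if s.color_id is None else s.color_id
                row[f"{side}_p_color"] = np.nan if s.p_color is None else s.p_color
                row[f"{side}_up_count"] = -1 if s.up_count is None else s.up_count
                row[f"{side}_orientations"] = (
                    "" if s.orientations is None
                    else "".join("1" if o else "0" for o in s.orientations)
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: Optional[TaskConfig] = None) -> "TaskSchedule":
        df = pd.read_csv(path, keep_default_na=False, na_values=[],
                         dtype={"left_orientations": str,
                                "right_orientations": str})
        config = config or TaskConfig()
        trials = []
        color_probs: dict[int, float] = {}
        for _, row in df.iterrows():
            stims = {}
            for side in SIDES:
                cid = int(row[f"{side}_color_id"])
                ori = str(row[f"{side}_orientations"])
                up = int(row[f"{side}_up_count"])
                stims[side] = Stimulus(
                    side=side,
                    color_id=None if cid < 0 else cid,
                    p_color=None if cid < 0 else float(row[f"{side}_p_color"]),
                    up_count=None if up < 0 else up,
                    orientations=None if up < 0 else tuple(c == "1" for c in ori),
                )
                if cid >= 0:
                    color_probs[cid] = float(row[f"{side}_p_color"])
            trials.append(
                Trial(
                    block=int(row["block"]),
                    trial=int(row["trial"]),
                    trial_type=str(row["trial_type"]),
                    left=stims["left"],
                    right=stims["right"],
                    is_practice=bool(int(row.get("is_practice", 0))),
                )
            )
        return cls(config=config, trials=trials, color_probs=color_probs)


# ---------------------------------------------------------------------------
# schedule generation
# ---------------------------------------------------------------------------

def _make_ring(up_count: int, n_cs: int, rng: np.random.Generator) -> tuple[bool, ...]:
    ori = np.zeros(n_cs, dtype=bool)
    ori[rng.choice(n_cs, size=up_count, replace=False)] = True
    return tuple(bool(o) for o in ori)


def _draw_stimulus(
    side: Side,
    trial_type: TrialType,
    colors: Sequence[int],
    color_probs: dict[int, float],
    config: TaskConfig,
    rng: np.random.Generator,
) -> Stimulus:
    color_id = p_color = up = ori = None
    if trial_type in ("combined", "color_only"):
        color_id = int(rng.choice(colors))
        p_color = color_probs[color_id]
    if trial_type in ("combined", "cs_only"):
        up = int(rng.choice(config.up_levels))
        ori = _make_ring(up, config.n_cs_per_stimulus, rng)
    return Stimulus(side=side, color_id=color_id, p_color=p_color,
                    up_count=up, orientations=ori)


def generate_task(config: TaskConfig, seed: int) -> TaskSchedule:
    """Generate a randomized schedule honouring the block design.

    Color-to-probability assignment is a per-participant permutation keyed by
    ``seed`` (the counterbalancing). Stimulus pairs are drawn uniformly over
    color x up-count combinations; fully identical left/right pairs are
    resampled unless ``config.allow_identical_pairs``.
    """
    rng = np.random.default_rng(seed)

    # counterbalanced color -> probability assignment
    color_probs: dict[int, float] = {}
    block_colors: list[list[int]] = []
    next_id = 0
    for probs in config.color_probs_per_block:
        ids = list(range(next_id, next_id + len(probs)))
        next_id += len(probs)
        perm = rng.permutation(len(probs))
        for cid, j in zip(ids, perm):
            color_probs[cid] = float(probs[j])
        block_colors.append(ids)

    trials: list[Trial] = []
    index = 0

    def emit(block: int, trial_type: TrialType, colors: Sequence[int],
             is_practice: bool) -> None:
        nonlocal index
        for _ in range(200):
            left = _draw_stimulus("left", trial_type, colors, color_probs, config, rng)
            right = _draw_stimulus("right", trial_type, colors, color_probs, config, rng)
            identical = (left.color_id == right.color_id
                         and left.up_count == right.up_count)
            if config.allow_identical_pairs or not identical:
                break
        trials.append(Trial(block=block, trial=index, trial_type=trial_type,
                            left=left, right=right, is_practice=is_practice))
        index += 1

    n_blocks = len(config.block_composition)
    for b in range(n_blocks):
        if b < len(block_colors):
            colors = block_colors[b]
        else:  # final block: all colors introduced so far
            colors = [c for ids in block_colors for c in ids]
        if config.include_practice and b < len(block_colors):
            for tt in TRIAL_TYPES:
                for _ in range(config.n_practice_per_type):
                    emit(b, tt, colors, is_practice=True)
        counts = config.block_composition[b]
        types = np.repeat(np.array(TRIAL_TYPES, dtype=object), counts)
        rng.shuffle(types)
        for tt in types:
            emit(b, str(tt), colors, is_practice=False)

    return TaskSchedule(config=config, trials=trials, color_probs=color_probs)


# ---------------------------------------------------------------------------
# reward process
# ---------------------------------------------------------------------------

def true_reward_prob(trial_type: TrialType, stimulus: Stimulus,
                     config: Optional[TaskConfig] = None) -> float:
    """Generative reward probability of choosing ``stimulus``.

    Combined trials average the color and C contributions (equal additive
    weights); single-component trials use the present component alone, with
    the up-count mapping {3: 0, 6: 0.5, 9: 1}.
    """
    config = config or TaskConfig()
    if trial_type == "combined":
        if not (stimulus.has_color and stimulus.has_cs):
            raise DataError("combined trial requires color and Cs")
        return 0.5 * (stimulus.p_color + config.cs_prob(stimulus.up_count))
    if trial_type == "cs_only":
        if not stimulus.has_cs:
            raise DataError("cs_only trial requires a C ring")
        return config.cs_prob(stimulus.up_count)
    if trial_type == "color_only":
        if not stimulus.has_color:
            raise DataError("color_only trial requires a color")
        return float(stimulus.p_color)
    raise DataError(f"unknown trial type {trial_type!r}")


def draw_reward(p: float, rng: np.random.Generator) -> int:
    """Bernoulli reward draw."""
    if not 0.0 <= p <= 1.0:
        raise DataError(f"reward probability {p} outside [0, 1]")
    return int(rng.random() < p)


def schedule_without_practice(schedule: TaskSchedule) -> TaskSchedule:
    """Analysis view of a schedule: practice trials removed."""
    return replace_trials(schedule, [t for t in schedule.trials if not t.is_practice])


def replace_trials(schedule: TaskSchedule, trials: list[Trial]) -> TaskSchedule:
    return TaskSchedule(config=schedule.config, trials=list(trials),
                        color_probs=dict(schedule.color_probs))
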