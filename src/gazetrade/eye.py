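"""Fixation-report processing: interest areas, repeat filtering, C counts.

Consumes EyeLink-style fixation reports (TSV with participant, trial,
t_start, duration, x, y; pixel coordinates, origin top-left).  Each fixation
is assigned to the nearest Landolt C center within an acceptance radius
(ties broken toward the lowest C index), repeat fixations on an
already-fixated C are discarded within a trial, and running up/down counts
per side are accumulated -- the observed-evidence inputs of the agent model
and the choice regressions.  Participants with 75% or fewer valid eye
samples are flagged for exclusion from gaze analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .task import DataError, TaskSchedule

__all__ = [
    "FixationRecord",
    "InterestArea",
    "InterestAreaMap",
    "ValidityReport",
    "read_fixation_report",
    "write_fixation_report",
    "assign_fixations",
    "drop_repeats",
    "cumulative_counts",
    "validity_filter",
    "VALIDITY_THRESHOLD",
]

VALIDITY_THRESHOLD = 0.75

REPORT_COLUMNS = ("participant", "trial", "t_start", "duration", "x", "y")


@dataclass(frozen=True)
class FixationRecord:
    participant: int
    trial: int
    t_start: float
    duration: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DataError("fixation duration must be positive")


@dataclass(frozen=True)
class InterestArea:
    trial: int
    side: str
    c_index: int
    x: float
    y: float
    radius: float


@dataclass
class InterestAreaMap:
    """Circular interest areas around each C, per trial and side."""

    areas: list[InterestArea] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_trial: dict[int, list[InterestArea]] = {}
        for a in self.areas:
            if a.radius <= 0:
                raise DataError("interest-area radius must be positive")
            self._by_trial.setdefault(a.trial, []).append(a)

    def for_trial(self, trial: int) -> list[InterestArea]:
        try:
            return self._by_trial[trial]
        except KeyError:
            raise DataError(f"no interest areas for trial {trial}")

    @property
    def trials(self) -> set[int]:
        return set(self._by_trial)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([a.__dict__ for a in self.areas])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "InterestAreaMap":
        df = pd.read_csv(path)
        return cls(areas=[
            InterestArea(trial=int(r.trial), side=str(r.side),
                         c_index=int(r.c_index), x=float(r.x), y=float(r.y),
                         radius=float(r.radius))
            for r in df.itertuples()
        ])


def read_fixation_report(path) -> tuple[list[FixationRecord], pd.DataFrame]:
    """Parse a fixation-report TSV.

    Malformed rows are collected into an error table (row number, reason)
    rather than silently dropped.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"fixation report missing columns: {missing}")
    records: list[FixationRecord] = []
    errors: list[dict] = []
    for i, row in df.iterrows():
        try:
            records.append(FixationRecord(
                participant=int(row["participant"]), trial=int(row["trial"]),
                t_start=float(row["t_start"]), duration=float(row["duration"]),
                x=float(row["x"]), y=float(row["y"]),
            ))
        except (ValueError, TypeError, DataError) as exc:
            errors.append({"row": int(i), "reason": str(exc)})
    return records, pd.DataFrame(errors, columns=["row", "reason"])


def write_fixation_report(records: Iterable[FixationRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t",
                                                       index=False)


def assign_fixations(records: Iterable[FixationRecord],
                     iamap: InterestAreaMap) -> pd.DataFrame:
    """Label each fixation with the nearest C within its acceptance radius.

    Fixations beyond every radius are labeled off-stimulus (side "", c_index
    -1) and retained.  Equidistant candidates resolve to the lowest C index
    (then left before right).
    """
    rows = []
    for r in records:
        areas = iamap.for_trial(r.trial)
        best: Optional[InterestArea] = None
        best_d = np.inf
        for a in areas:
            d = float(np.hypot(r.x - a.x, r.y - a.y))
            if d > a.radius:
                continue
            key = (d, a.c_index, 0 if a.side == "left" else 1)
            if best is None or key < (best_d, best.c_index,
                                      0 if best.side == "left" else 1):
                best, best_d = a, d
        rows.append({
            "participant": r.participant, "trial": r.trial,
            "t_start": r.t_start, "duration": r.duration,
            "x": r.x, "y": r.y,
            "side": best.side if best else "",
            "c_index": best.c_index if best else -1,
        })
    df = pd.DataFrame(rows, columns=["participant", "trial", "t_start",
                                     "duration", "x", "y", "side", "c_index"])
    return df.sort_values(["participant", "trial", "t_start"],
                          kind="stable").reset_index(drop=True)


def drop_repeats(labeled: pd.DataFrame) -> pd.DataFrame:
    """Keep only the first fixation per (trial, side, C) within participant.

    Off-stimulus fixations (c_index < 0) are removed from the counting
    stream entirely.  Idempotent.
    """
    on_stim = labeled[labeled["c_index"] >= 0]
    kept = on_stim.drop_duplicates(
        subset=["participant", "trial", "side", "c_index"], keep="first")
    return kept.reset_index(drop=True)


def cumulative_counts(filtered: pd.DataFrame,
                      schedule: TaskSchedule) -> pd.DataFrame:
    """Running up/down counts per side after each retained fixation.

    One row per fixation step, with the cumulative counts *after* that
    fixation; the final row of a trial carries the totals that feed the
    observed-Cs predictors.
    """
    by_index = {t.trial: t for t in schedule}
    rows = []
    for (pid, trial_idx), grp in filtered.groupby(["participant", "trial"],
                                                  sort=True):
        try:
            trial = by_index[int(trial_idx)]
        except KeyError:
            raise DataError(f"trial {trial_idx} absent from schedule")
        counts = {("left", True): 0, ("left", False): 0,
                  ("right", True): 0, ("right", False): 0}
        grp = grp.sort_values("t_start", kind="stable")
        for step, r in enumerate(grp.itertuples(), start=1):
            stim = trial.stimulus(r.side)
            if stim.orientations is None or not 0 <= r.c_index < len(
                    stim.orientations):
                raise DataError(
                    f"fixated C {r.c_index} absent from trial {trial_idx}")
            up = bool(stim.orientations[r.c_index])
            counts[(r.side, up)] += 1
            rows.append({
                "participant": pid, "trial": int(trial_idx), "step": step,
                "side": r.side, "c_index": int(r.c_index), "up": int(up),
                "left_up": counts[("left", True)],
                "left_down": counts[("left", False)],
                "right_up": counts[("right", True)],
                "right_down": counts[("right", False)],
            })
    cols = ["participant", "trial", "step", "side", "c_index", "up",
            "left_up", "left_down", "right_up", "right_down"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class ValidityReport:
    """Per-participant valid-sample fractions and inclusion flags."""

    table: pd.DataFrame  # participant, validity, included

    def included(self) -> list[int]:
        return list(self.table.loc[self.table["included"], "participant"])

    def excluded(self) -> list[int]:
        return list(self.table.loc[~self.table["included"], "participant"])


def validity_filter(validity: pd.DataFrame,
                    threshold: float = VALIDITY_THRESHOLD) -> ValidityReport:
    """Flag participants for gaze analyses: included iff validity is
    strictly above the threshold (75% exactly is excluded)."""
    t = validity.copy()
    if not {"participant", "validity"} <= set(t.columns):
        raise DataError("validity table needs participant and validity columns")
    if ((t["validity"] < 0) | (t["validity"] > 1)).any():
        raise DataError("validity fractions must lie in [0, 1]")
    t["included"] = t["validity"] > threshold
    return ValidityReport(table=t.reset_index(drop=True))
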