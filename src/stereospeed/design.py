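"""Experimental design: conditions, stimulus ladders, trial schedules, QC.

Eight conditions cross four stimulus families (World, World Control, Retina,
Retina Control) with two speed classes (Fast ≈ 40 cm/s, Slow ≈ 20 cm/s world
standard).  Each condition is measured with a 7-level method of constant
stimuli: level 1 is the standard (no speed change) and levels 2–7 step the
pre-change speed down and the post-change speed up by equal amounts so that
every level covers the same world distance in the same duration — removing
distance and duration as cues.  The discriminandum is the proportion speed
change at the changepoint, (c - b)/c, computed on retinal speeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .geometry import (
    SpeedChangeInterval,
    ViewingGeometry,
    build_world_interval,
    trace_retinal,
    world_to_angle,
    ARCMIN_PER_RAD,
)

__all__ = [
    "StimulusFamily",
    "SpeedClass",
    "Condition",
    "CONDITIONS",
    "LevelStep",
    "level_ladder",
    "proportion_speed_change",
    "condition_levels",
    "build_experiment",
    "qc_exclude",
    "passes_training",
    "speed_tables",
    "N_LEVELS",
    "N_BLOCKS",
    "TRIALS_PER_LEVEL",
    "FAST_STANDARD_V",
    "SLOW_STANDARD_V",
    "FAST_STEP",
    "SLOW_STEP",
    "TRAINING_SPEEDS_ARCMIN",
]

N_LEVELS = 7
N_BLOCKS = 3
TRIALS_PER_LEVEL = 10
DURATION_S = 1.0
CHANGE_TIME_S = 0.5
STATIC_LEAD_S = 0.25

FAST_STANDARD_V = 40.0  # cm/s
SLOW_STANDARD_V = 20.0
FAST_STEP = 5.0
SLOW_STEP = 2.5

#: training-block retinal speeds (arcmin/s), documented constants only:
#: drifting-grating standard, and (before, after) pairs for hard/easy changes
TRAINING_SPEEDS_ARCMIN = {
    "standard": 283.4,
    "hard": (212.6, 354.1),
    "easy": (70.9, 495.3),
}


class StimulusFamily(str, Enum):
    WORLD = "World"
    WORLD_CONTROL = "WorldControl"
    RETINA = "Retina"
    RETINA_CONTROL = "RetinaControl"


class SpeedClass(str, Enum):
    FAST = "Fast"
    SLOW = "Slow"


@dataclass(frozen=True)
class Condition:
    family: StimulusFamily
    speed: SpeedClass

    @property
    def label(self) -> str:
        return f"{self.family.value}-{self.speed.value}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        fam, spd = label.rsplit("-", 1)
        return cls(StimulusFamily(fam), SpeedClass(spd))

    @property
    def is_world_kinematics(self) -> bool:
        """True for families rendered from constant world speed."""
        return self.family in (StimulusFamily.WORLD, StimulusFamily.WORLD_CONTROL)


#: the 8 experimental conditions
CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(f, s) for f, s in itertools.product(StimulusFamily, SpeedClass)
)


@dataclass(frozen=True)
class LevelStep:
    """One rung of the constant-stimuli ladder (world speeds, cm/s)."""

    level: int
    v_before: float
    v_after: float


def level_ladder(standard_v: float, step: float, n_levels: int = N_LEVELS) -> list[LevelStep]:
    """Build the method-of-constant-stimuli ladder of world speeds.

    Level k runs at ``standard_v - (k-1)*step`` before the change and
    ``standard_v + (k-1)*step`` after it, so the mean speed — hence the
    distance covered in the fixed duration — is the same at every level.
    Fast conditions use a 5 cm/s step (level 7: 10→70), Slow 2.5 cm/s
    (level 7: 5→35).
    """
    if standard_v <= 0 or step <= 0:
        raise ValueError("standard_v and step must be positive")
    if standard_v - (n_levels - 1) * step <= 0:
        raise ValueError("ladder reaches a non-positive pre-change speed")
    return [
        LevelStep(k, standard_v - (k - 1) * step, standard_v + (k - 1) * step)
        for k in range(1, n_levels + 1)
    ]


def proportion_speed_change(b: float, c: float) -> float:
    """Proportion speed change at the changepoint: ``(c - b) / c``.

    ``b`` and ``c`` are the retinal speeds immediately before and after the
    step; the post-change speed is the denominator.
    """
    if c <= 0:
        raise ValueError("post-change speed c must be positive")
    if b > c:
        raise ValueError("require b <= c (speed steps up)")
    return (c - b) / c


def _ladder_for(speed: SpeedClass) -> list[LevelStep]:
    if speed is SpeedClass.FAST:
        return level_ladder(FAST_STANDARD_V, FAST_STEP)
    return level_ladder(SLOW_STANDARD_V, SLOW_STEP)


def _world_interval(step: LevelStep) -> SpeedChangeInterval:
    return SpeedChangeInterval(
        v_before=step.v_before,
        v_after=step.v_after,
        change_time_s=CHANGE_TIME_S,
        duration_s=DURATION_S,
        static_lead_s=STATIC_LEAD_S,
    )


def mean_retinal_speed(speed: SpeedClass, geom: ViewingGeometry) -> float:
    """Whole-interval mean cyclopean retinal speed of the world standard (arcmin/s).

    Total angular displacement over duration; every level of a world ladder
    shares it because all levels traverse the same depth span.  This is the
    derived constant speed of the matching ``Retina`` standard (the stimulus
    tables print slightly different constants, available as config
    overrides).
    """
    step = _ladder_for(speed)[0]
    traj = build_world_interval(_world_interval(step), geom)
    x = geom.half_separation_cm
    th0 = float(world_to_angle(x, traj.z0)) * ARCMIN_PER_RAD
    th1 = float(world_to_angle(x, traj.z1)) * ARCMIN_PER_RAD
    return (th1 - th0) / traj.duration_s


def _retina_level_speeds(
    step: LevelStep, speed: SpeedClass, geom: ViewingGeometry
) -> tuple[float, float]:
    """Piecewise retinal speeds (arcmin/s) of a constant-retinal-speed level.

    The world ladder's speed ratios are scaled onto the mean retinal speed:
    level k runs at ``s̄ · v_before,k / v_standard`` then
    ``s̄ · v_after,k / v_standard``.  The halves sum to ``2 s̄``, so total
    retinal displacement is conserved across levels (mirroring the world
    ladder's distance conservation), the standard is genuinely constant, and
    the changepoint proportion (c-b)/c equals the world family's.
    """
    standard_v = FAST_STANDARD_V if speed is SpeedClass.FAST else SLOW_STANDARD_V
    sbar = mean_retinal_speed(speed, geom)
    return sbar * step.v_before / standard_v, sbar * step.v_after / standard_v


def condition_levels(geom: ViewingGeometry | None = None) -> pd.DataFrame:
    """Level table for all 8 conditions.

    Columns: condition, level, v_before_world, v_after_world (cm/s; NaN for
    Retina families), b, c (retinal speeds just before/after the changepoint,
    arcmin/s) and prop_change = (c-b)/c, the stimulus intensity the observer
    discriminates.  World and World Control share kinematics (the control is
    the duplicated left half-image of the same motion); Retina and Retina
    Control share the same speeds.
    """
    geom = geom or ViewingGeometry()
    rows = []
    for cond in CONDITIONS:
        for step in _ladder_for(cond.speed):
            if cond.is_world_kinematics:
                trace = trace_retinal(build_world_interval(_world_interval(step), geom), geom)
                b, c = trace.b, trace.c
                vb, va = step.v_before, step.v_after
            else:
                b, c = _retina_level_speeds(step, cond.speed, geom)
                vb, va = np.nan, np.nan
            rows.append(
                {
                    "condition": cond.label,
                    "level": step.level,
                    "v_before_world": vb,
                    "v_after_world": va,
                    "b": b,
                    "c": c,
                    "prop_change": proportion_speed_change(b, c),
                }
            )
    return pd.DataFrame(rows)


def speed_tables(geom: ViewingGeometry | None = None) -> pd.DataFrame:
    """Per-condition, per-level a/b/c/d retinal speeds (arcmin/s) plus world speeds.

    The CSV analogue of the stimulus speed tables: for world-kinematics
    conditions a–d are cyclopean instantaneous speeds at onset, the two sides
    of the change, and offset; for retina conditions speeds are piecewise
    constant so a = b and c = d.
    """
    geom = geom or ViewingGeometry()
    rows = []
    for cond in CONDITIONS:
        for step in _ladder_for(cond.speed):
            if cond.is_world_kinematics:
                trace = trace_retinal(build_world_interval(_world_interval(step), geom), geom)
                a, b, c, d = trace.a, trace.b, trace.c, trace.d
            else:
                b, c = _retina_level_speeds(step, cond.speed, geom)
                a, d = b, c
            rows.append(
                {
                    "condition": cond.label,
                    "level": step.level,
                    "v_before_world": step.v_before if cond.is_world_kinematics else np.nan,
                    "v_after_world": step.v_after if cond.is_world_kinematics else np.nan,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                }
            )
    return pd.DataFrame(rows)


TRIAL_COLUMNS = ["participant", "condition", "level", "block", "change_interval", "correct"]


def build_experiment(
    participants,
    conditions: tuple[Condition, ...] = CONDITIONS,
    n_blocks: int = N_BLOCKS,
    trials_per_level: int = TRIALS_PER_LEVEL,
    n_levels: int = N_LEVELS,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build a reproducible 2IFC trial schedule (responses unfilled).

    Per participant, blocks are ordered at random across conditions; within a
    block each level appears ``trials_per_level`` times in shuffled order and
    the change-bearing interval (1 or 2) is drawn uniformly per trial.  With
    the defaults each participant receives 8 × 210 = 1680 trials.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for p in participants:
        blocks = [(c.label, b) for c in conditions for b in range(1, n_blocks + 1)]
        order = rng.permutation(len(blocks))
        for idx in order:
            cond_label, block = blocks[idx]
            levels = np.repeat(np.arange(1, n_levels + 1), trials_per_level)
            rng.shuffle(levels)
            frames.append(
                pd.DataFrame(
                    {
                        "participant": p,
                        "condition": cond_label,
                        "level": levels,
                        "block": block,
                        "change_interval": rng.integers(1, 3, size=levels.size),
                        "correct": pd.array([pd.NA] * levels.size, dtype="Int64"),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def qc_exclude(
    trials: pd.DataFrame,
    top_level: int = N_LEVELS,
    min_accuracy: float = 0.8,
    min_failing_conditions: int = 2,
) -> pd.DataFrame:
    """Apply the participant exclusion rule to a completed trial table.

    A participant is excluded iff their accuracy at the highest speed-change
    level falls below ``min_accuracy`` in at least ``min_failing_conditions``
    conditions.  Returns one row per participant with columns
    ``retained`` (bool) and ``reason``.
    """
    required = {"participant", "condition", "level", "correct"}
    missing_cols = required - set(trials.columns)
    if missing_cols:
        raise ValueError(f"trial table missing columns: {sorted(missing_cols)}")
    if trials["correct"].isna().any():
        raise ValueError("trial table contains unfilled responses")
    conditions = sorted(trials["condition"].unique())
    out = []
    for p, sub in trials.groupby("participant", sort=True):
        top = sub[sub["level"] == top_level]
        present = set(top["condition"])
        absent = [c for c in conditions if c not in present]
        if absent:
            raise ValueError(
                f"participant {p!r} has no level-{top_level} trials in: {absent}"
            )
        acc = top.groupby("condition")["correct"].mean()
        failing = sorted(acc.index[acc < min_accuracy])
        excluded = len(failing) >= min_failing_conditions
        reason = (
            f"accuracy < {min_accuracy:g} at level {top_level} in {len(failing)} "
            f"condition(s): {', '.join(failing)}"
            if excluded
            else ""
        )
        out.append({"participant": p, "retained": not excluded, "reason": reason})
    return pd.DataFrame(out)


def passes_training(n_correct: int, n_trials: int = 60, required: int = 50) -> bool:
    """Final-training-block criterion: at least ``required`` of ``n_trials`` correct."""
    if not 0 <= n_correct <= n_trials:
        raise ValueError("n_correct must lie in [0, n_trials]")
    return n_correct >= required
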