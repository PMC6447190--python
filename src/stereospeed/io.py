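"""Configuration and CSV interchange.

All tabular interchange is plain CSV (comma, UTF-8, header row), the format
psychophysics data are typically deposited in.  Configuration is a YAML file
that round-trips losslessly through :class:`RunConfig`; unknown keys are
rejected rather than ignored so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .design import TRIAL_COLUMNS

__all__ = [
    "RunConfig",
    "GeometrySection",
    "DesignSection",
    "FitSection",
    "StatsSection",
    "CohortSection",
    "read_trials",
    "write_trials",
]

#: printed stimulus-table constants for the constant-retinal-speed families
#: (arcmin/s): standard speed and (before, after) at the maximum change level.
#: These are the published values; the derived time-average route gives
#: slightly different numbers (see geometry.derive_retina_speed).
PRINTED_RETINA_SPEEDS = {
    "Retina-Fast": {"standard": 47.6, "max_change": [7.6, 87.4]},
    "RetinaControl-Fast": {"standard": 47.6, "max_change": [7.7, 87.5]},
    "Retina-Slow": {"standard": 22.3, "max_change": [4.6, 40.0]},
    "RetinaControl-Slow": {"standard": 22.3, "max_change": [4.6, 40.1]},
}


@dataclass
class GeometrySection:
    viewing_distance_cm: float = 97.0
    ipd_cm: float = 6.5
    refresh_hz: float = 85.0
    half_separation_cm: float = 3.0


@dataclass
class DesignSection:
    fast_standard_v: float = 40.0
    slow_standard_v: float = 20.0
    fast_step: float = 5.0
    slow_step: float = 2.5
    n_levels: int = 7
    n_blocks: int = 3
    trials_per_level: int = 10
    duration_s: float = 1.0
    change_time_s: float = 0.5
    static_lead_s: float = 0.25
    retina_speed_overrides: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in PRINTED_RETINA_SPEEDS.items()}
    )


@dataclass
class FitSection:
    guess: float = 0.5
    lapse: float = 0.0


@dataclass
class StatsSection:
    ci_level: float = 0.95
    cauchy_scale: float = 0.5
    bayes_factor: bool = True


@dataclass
class CohortSection:
    n_participants: int = 9
    scenario: str = "suppression"
    between_sd: float = 0.08
    sigma_ratio: float = 0.5
    lapse: float = 0.0


@dataclass
class RunConfig:
    """Full run configuration; YAML round-trip is the contract."""

    geometry: GeometrySection = field(default_factory=GeometrySection)
    design: DesignSection = field(default_factory=DesignSection)
    fit: FitSection = field(default_factory=FitSection)
    stats: StatsSection = field(default_factory=StatsSection)
    cohort: CohortSection = field(default_factory=CohortSection)
    seed: int = 0
    out_dir: str = "."

    _SECTIONS = {
        "geometry": GeometrySection,
        "design": DesignSection,
        "fit": FitSection,
        "stats": StatsSection,
        "cohort": CohortSection,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        scalar_keys = {"seed", "out_dir"}
        unknown = set(data) - set(cls._SECTIONS) - scalar_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            sect = data.get(name, {})
            valid = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(sect) - valid
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            kwargs[name] = section_cls(**sect)
        for key in scalar_keys:
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
        return cls.from_dict(data)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def viewing_geometry(self):
        from .geometry import ViewingGeometry

        g = self.geometry
        return ViewingGeometry(
            viewing_distance_cm=g.viewing_distance_cm,
            ipd_cm=g.ipd_cm,
            refresh_hz=g.refresh_hz,
            half_separation_cm=g.half_separation_cm,
        )


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with the canonical header."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV.

    Checks the header, integer-codes the design columns and requires binary
    (0/1) responses; malformed rows are reported with their file line
    numbers.  An empty file yields an empty table with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty and len(df.columns) <= 1:
        warnings.warn(f"{path}: empty trial file", UserWarning, stacklevel=2)
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df[TRIAL_COLUMNS]
    if df.empty:
        warnings.warn(f"{path}: empty trial file", UserWarning, stacklevel=2)
        return df
    bad_lines = []
    for col in ("level", "block", "change_interval", "correct"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if col == "change_interval":
            bad |= ~numeric.isin([1, 2])
        if col == "correct":
            bad |= ~numeric.isin([0, 1])
        # +2: header line plus 1-based numbering
        bad_lines.extend((df.index[bad] + 2).tolist())
        df[col] = numeric
    if bad_lines:
        raise ValueError(
            f"{path}: malformed rows at line(s) {sorted(set(bad_lines))[:20]}"
        )
    for col in ("level", "block", "change_interval", "correct"):
        df[col] = df[col].astype(int)
    df["correct"] = df["correct"].astype("Int64")
    return df
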