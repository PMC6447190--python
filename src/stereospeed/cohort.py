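"""Synthetic cohorts with the study's full trial structure.

A cohort emulates the deposited dataset's shape — 9 participants × 8
conditions × 7 levels × 3 blocks × 10 trials — without any download: each
participant's per-condition 75% threshold is drawn from a truncated-normal
population, a seeded 2IFC observer produces every binary response, and the
downstream pipeline (psychometric fitting, repeated-measures ANOVA) can then
be exercised end to end.

Scenarios fix the population condition means:

``null``
    All eight conditions share one mean — the no-effect reference for
    type-I calibration of the World-vs-Retina comparison.
``suppression``
    Motion-in-depth (main) conditions are harder than their lateral
    controls: control means are 0.7× the main means, the stereomotion-
    suppression pattern.
``fast-advantage``
    A speed effect confined to the constant-retinal-speed pair, with the
    Retina-Control-Fast condition easiest (driving the interaction).

Population thresholds sit in the 0.20–0.37 band typical of speed-change
discrimination; between-participant sd defaults to 0.08 and each observer's
spread is half their threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .design import CONDITIONS, build_experiment, condition_levels
from .geometry import ViewingGeometry
from .observer import ObserverModel, simulate_responses
from .psychofit import fit_thresholds
from .stats import rm_anova_2x2

__all__ = [
    "SCENARIOS",
    "CohortSpec",
    "scenario_means",
    "generate_cohort",
    "cohort_thresholds",
    "threshold_wide",
    "family_comparison_cells",
    "analyze_cohort",
    "COMPARISONS",
    "recovery_study",
]

_MAIN = ("World-Fast", "World-Slow", "Retina-Fast", "Retina-Slow")
_CONTROL = ("WorldControl-Fast", "WorldControl-Slow",
            "RetinaControl-Fast", "RetinaControl-Slow")

SCENARIOS: dict[str, dict[str, float]] = {
    "null": {c.label: 0.28 for c in CONDITIONS},
    "suppression": {
        "World-Fast": 0.30,
        "World-Slow": 0.30,
        "Retina-Fast": 0.30,
        "Retina-Slow": 0.30,
        "WorldControl-Fast": 0.21,
        "WorldControl-Slow": 0.21,
        "RetinaControl-Fast": 0.21,
        "RetinaControl-Slow": 0.21,
    },
    "fast-advantage": {
        "World-Fast": 0.30,
        "World-Slow": 0.30,
        "WorldControl-Fast": 0.30,
        "WorldControl-Slow": 0.30,
        "Retina-Fast": 0.28,
        "Retina-Slow": 0.32,
        "RetinaControl-Fast": 0.20,
        "RetinaControl-Slow": 0.30,
    },
}


def scenario_means(scenario: str) -> dict[str, float]:
    """Population mean thresholds per condition for a named scenario."""
    try:
        return dict(SCENARIOS[scenario])
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario!r}; available: {sorted(SCENARIOS)}"
        ) from None


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_participants: int = 9
    scenario: str = "suppression"
    between_sd: float = 0.08
    sigma_ratio: float = 0.5
    lapse: float = 0.0
    seed: int | None = None
    mean_overrides: dict[str, float] = field(default_factory=dict)
    threshold_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least 1 participant")
        if self.between_sd < 0:
            raise ValueError("between_sd must be non-negative")
        if self.sigma_ratio <= 0:
            raise ValueError("sigma_ratio must be positive")
        means = self.condition_means
        if any(m <= 0 for m in means.values()):
            raise ValueError("population mean thresholds must be positive")

    @property
    def condition_means(self) -> dict[str, float]:
        means = scenario_means(self.scenario)
        unknown = set(self.mean_overrides) - set(means)
        if unknown:
            raise ValueError(f"mean_overrides for unknown conditions: {sorted(unknown)}")
        means.update(self.mean_overrides)
        return means


def _draw_alphas(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Participant × condition true thresholds, truncated below at the floor."""
    means = spec.condition_means
    out = {}
    for cond in CONDITIONS:
        mu = means[cond.label]
        if spec.between_sd == 0:
            vals = np.full(spec.n_participants, mu)
        else:
            a = (spec.threshold_floor - mu) / spec.between_sd
            vals = truncnorm.rvs(
                a, np.inf, loc=mu, scale=spec.between_sd,
                size=spec.n_participants, random_state=rng,
            )
        out[cond.label] = vals
    idx = [f"p{i + 1:02d}" for i in range(spec.n_participants)]
    return pd.DataFrame(out, index=idx)


def generate_cohort(
    spec: CohortSpec, geom: ViewingGeometry | None = None,
    return_truth: bool = False,
):
    """Simulate a full cohort of trial records.

    Draws per-participant true thresholds from the scenario's population,
    builds the full randomized schedule, and fills every response through
    the observer model.  Reproducible under ``spec.seed``.  With
    ``return_truth=True`` also returns the participant × condition table of
    true thresholds.
    """
    rng = np.random.default_rng(spec.seed)
    alphas = _draw_alphas(spec, rng)
    levels = condition_levels(geom)
    schedule = build_experiment(list(alphas.index), seed=rng)
    models = {
        (p, cond): ObserverModel(
            alpha=alphas.loc[p, cond],
            sigma=spec.sigma_ratio * alphas.loc[p, cond],
            lapse=spec.lapse,
        )
        for p in alphas.index
        for cond in alphas.columns
    }
    trials = simulate_responses(schedule, models, levels, seed=rng)
    return (trials, alphas) if return_truth else trials


def cohort_thresholds(
    trials: pd.DataFrame, geom: ViewingGeometry | None = None
) -> pd.DataFrame:
    """Fit 75% thresholds for every (participant, condition) in a cohort."""
    return fit_thresholds(trials, condition_levels(geom))


def threshold_wide(thresholds: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long threshold table to participants × conditions."""
    return thresholds.pivot(index="participant", columns="condition", values="threshold")


#: the three planned family comparisons: name -> (family A, family B)
COMPARISONS = {
    "World vs Retina": ("World", "Retina"),
    "World vs WorldControl": ("World", "WorldControl"),
    "Retina vs RetinaControl": ("Retina", "RetinaControl"),
}


def family_comparison_cells(wide: pd.DataFrame, family_a: str, family_b: str) -> np.ndarray:
    """Assemble the (n, 2, 2) cell array for a family × speed comparison.

    Axis 1 indexes (family_a, family_b), axis 2 (Fast, Slow).
    """
    cols = [[f"{family_a}-Fast", f"{family_a}-Slow"],
            [f"{family_b}-Fast", f"{family_b}-Slow"]]
    flat = [c for pair in cols for c in pair]
    missing = [c for c in flat if c not in wide.columns]
    if missing:
        raise ValueError(f"threshold table missing conditions: {missing}")
    return wide[flat].to_numpy().reshape(len(wide), 2, 2)


def analyze_cohort(
    wide: pd.DataFrame, bayes_factor: bool = False, cauchy_scale: float = 0.5
) -> pd.DataFrame:
    """Run the three planned 2×2 RM-ANOVAs on a wide threshold table."""
    frames = []
    for name, (fam_a, fam_b) in COMPARISONS.items():
        cells = family_comparison_cells(wide, fam_a, fam_b)
        res = rm_anova_2x2(
            cells, factor_a=name, factor_b="Fast vs Slow",
            bayes_factor=bayes_factor, cauchy_scale=cauchy_scale,
        )
        frame = res.as_frame()
        frame.insert(0, "comparison", name)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def recovery_study(
    n_cohorts: int = 20,
    scenario: str = "suppression",
    comparison: str = "World vs WorldControl",
    alpha_level: float = 0.05,
    seed: int | None = None,
    spec_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Replicate the full pipeline over many cohorts.

    For each replicate: generate a cohort, fit thresholds, run the requested
    family comparison, and record the main-effect p value plus the mean
    fitted and true thresholds per family.  The rejection rate estimates
    type-I error under ``scenario='null'`` and power otherwise.
    """
    fam_a, fam_b = COMPARISONS[comparison]
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cohorts):
        spec = CohortSpec(
            scenario=scenario,
            seed=int(rng.integers(2**31)),
            **(spec_kwargs or {}),
        )
        trials, truth = generate_cohort(spec, return_truth=True)
        wide = threshold_wide(cohort_thresholds(trials))
        cells = family_comparison_cells(wide, fam_a, fam_b)
        res = rm_anova_2x2(cells, factor_a=comparison, factor_b="Fast vs Slow")
        eff = res[comparison]
        cols_a = [f"{fam_a}-Fast", f"{fam_a}-Slow"]
        cols_b = [f"{fam_b}-Fast", f"{fam_b}-Slow"]
        rows.append(
            {
                "replicate": i,
                "scenario": scenario,
                "comparison": comparison,
                "F": eff.F,
                "p": eff.p,
                "rejected": eff.p < alpha_level,
                "mean_fitted_a": wide[cols_a].to_numpy().mean(),
                "mean_fitted_b": wide[cols_b].to_numpy().mean(),
                "mean_true_a": truth[cols_a].to_numpy().mean(),
                "mean_true_b": truth[cols_b].to_numpy().mean(),
            }
        )
    return pd.DataFrame(rows)
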