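"""Synthetic 2IFC observers.

An observer is a ground-truth psychometric model: the probability of
correctly identifying the change-bearing interval at proportion speed change
``x`` is a cumulative normal scaled between the 2IFC guess rate (0.5) and
1 minus the lapse rate.  Trials are independent Bernoulli draws — the main
experiment gives no feedback, so no learning or sequential dependence is
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["ObserverModel", "p_correct", "simulate_responses"]


@dataclass(frozen=True)
class ObserverModel:
    """Ground-truth cumulative-normal observer.

    ``alpha`` is the proportion speed change yielding 75% correct (the
    location parameter under guess 0.5, lapse 0); ``sigma`` the spread in
    the same units.
    """

    alpha: float
    sigma: float
    guess: float = 0.5
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.lapse <= 0.06:
            raise ValueError("lapse must lie in [0, 0.06]")
        if not 0.0 <= self.guess < 1.0:
            raise ValueError("guess must lie in [0, 1)")


def p_correct(x, model: ObserverModel):
    """Probability of a correct 2IFC response at stimulus intensity ``x``.

    ``guess + (1 - guess - lapse) * Phi((x - alpha) / sigma)``; bounded in
    ``[guess, 1 - lapse]`` and nondecreasing in ``x``.
    """
    x = np.asarray(x, dtype=float)
    p = model.guess + (1.0 - model.guess - model.lapse) * norm.cdf(
        (x - model.alpha) / model.sigma
    )
    return p if p.ndim else float(p)


def simulate_responses(
    schedule: pd.DataFrame,
    models: Mapping[str, ObserverModel],
    level_intensity: pd.DataFrame,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill the ``correct`` column of a trial schedule with observer draws.

    ``models`` maps condition label → :class:`ObserverModel` (a mapping keyed
    by ``(participant, condition)`` tuples is also accepted for heterogeneous
    cohorts); ``level_intensity`` is the design-module level table with
    columns (condition, level, prop_change).  Each trial is an independent
    Bernoulli draw with probability :func:`p_correct` at the trial's
    intensity; the draw is reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    xmap = level_intensity.set_index(["condition", "level"])["prop_change"]
    out = schedule.copy()
    try:
        x = xmap.loc[list(zip(out["condition"], out["level"]))].to_numpy()
    except KeyError as err:
        raise ValueError(f"no stimulus intensity for condition/level {err}") from err

    per_participant = bool(models) and isinstance(next(iter(models.keys())), tuple)
    if per_participant:
        keys = pd.Series(list(zip(out["participant"], out["condition"])), index=out.index)
    else:
        keys = out["condition"]
    p = np.empty(len(out))
    for key, idx in keys.groupby(keys).groups.items():
        try:
            model = models[key]
        except KeyError:
            raise ValueError(f"no observer model for {key!r}") from None
        loc = out.index.get_indexer(idx)
        p[loc] = p_correct(x[loc], model)
    out["correct"] = pd.array((rng.random(len(out)) < p).astype(int), dtype="Int64")
    return out
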