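"""Repeated-measures statistics on threshold tables.

The planned analysis is three 2×2 within-subject ANOVAs on 75% thresholds
(stimulus family × speed class), each effect tested against its own
participant-by-effect interaction.  With two-level factors every effect has
one numerator degree of freedom, so the classical univariate decomposition
is algebraically a paired t-test on per-participant contrast scores:
``F = t²`` with ``df = (1, n-1)``, and partial eta squared reduces to
``SS_effect / (SS_effect + SS_error) = F / (F + df_den)``.  This module
computes the decomposition that way — exact and fast enough for
10,000-replicate calibration studies.

Bayesian evidence for a paired contrast uses the JZS Bayes factor: a Cauchy
prior (centre 0, width ``r``) on the standardised effect size, with BF10 the
ratio of the marginal likelihood of the observed t statistic under that
prior to its likelihood under the point null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "AnovaResult",
    "rm_anova_2x2",
    "between_subject_ci",
    "jzs_paired_bf",
    "jzs_bf_from_t",
]


@dataclass(frozen=True)
class EffectResult:
    """One tested effect of a within-subject ANOVA."""

    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    bf10: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    """All effects of one 2×2 repeated-measures ANOVA."""

    factor_a: str
    factor_b: str
    effects: dict[str, EffectResult] = field(default_factory=dict)

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.name,
                    "F": e.F,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "bf10": e.bf10,
                }
                for e in self.effects.values()
            ]
        )


def _as_cells(table, factor_a, factor_b) -> np.ndarray:
    """Coerce input to an (n_subjects, 2, 2) cell array."""
    if isinstance(table, pd.DataFrame):
        required = {"participant", factor_a, factor_b, "value"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"long table missing columns: {sorted(missing)}")
        pivot = table.pivot_table(
            index="participant", columns=[factor_a, factor_b], values="value"
        )
        if pivot.isna().any().any():
            bad = [c for c in pivot.columns if pivot[c].isna().any()]
            raise ValueError(f"missing cells in within-subject table: {bad}")
        if pivot.shape[1] != 4:
            raise ValueError("need exactly 2 levels per factor (4 cells)")
        cells = pivot.to_numpy().reshape(len(pivot), 2, 2)
    else:
        cells = np.asarray(table, dtype=float)
        if cells.ndim != 3 or cells.shape[1:] != (2, 2):
            raise ValueError("array input must have shape (n_subjects, 2, 2)")
        if np.isnan(cells).any():
            raise ValueError("missing cells in within-subject table")
    if cells.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    return cells


def _effect_from_contrast(name: str, contrast: np.ndarray,
                          bf_scale: float | None) -> EffectResult:
    n = contrast.size
    df_den = n - 1
    mean = float(contrast.mean())
    ss_err = float(np.sum((contrast - mean) ** 2))
    ss_eff = n * mean**2
    if ss_err == 0.0:
        if ss_eff == 0.0:
            F, p, pes = 0.0, 1.0, 0.0
        else:
            warnings.warn(
                f"zero error variance for effect {name!r}: F reported as infinite",
                RuntimeWarning,
                stacklevel=3,
            )
            F, p, pes = float("inf"), 0.0, 1.0
    else:
        F = df_den * ss_eff / ss_err
        p = float(sps.f.sf(F, 1, df_den))
        pes = ss_eff / (ss_eff + ss_err)
    bf10 = None
    if bf_scale is not None and ss_err > 0.0:
        bf10 = jzs_paired_bf(contrast, cauchy_scale=bf_scale)
    return EffectResult(name, float(F), 1, df_den, p, float(pes), bf10)


def rm_anova_2x2(
    table,
    factor_a: str = "A",
    factor_b: str = "B",
    bayes_factor: bool = False,
    cauchy_scale: float = 0.5,
) -> AnovaResult:
    """2×2 repeated-measures ANOVA with partial eta squared.

    Parameters
    ----------
    table:
        Either an ``(n_subjects, 2, 2)`` array of cell values (axis 1 =
        factor A, axis 2 = factor B) or a long DataFrame with columns
        ``participant``, ``factor_a``, ``factor_b``, ``value``.
    factor_a, factor_b:
        Effect names (and, for long input, column names).
    bayes_factor:
        If true, attach the JZS paired-contrast BF10 to each effect
        (Cauchy prior width ``cauchy_scale``).

    Each effect is tested against its own subject-by-effect interaction
    mean square; sphericity corrections are moot with single-df effects.
    """
    cells = _as_cells(table, factor_a, factor_b)
    scale = cauchy_scale if bayes_factor else None
    # per-subject contrast scores (differences of marginal means)
    con_a = cells[:, 1, :].mean(axis=1) - cells[:, 0, :].mean(axis=1)
    con_b = cells[:, :, 1].mean(axis=1) - cells[:, :, 0].mean(axis=1)
    con_ab = (cells[:, 1, 1] - cells[:, 1, 0] - cells[:, 0, 1] + cells[:, 0, 0]) / 2.0
    inter = f"{factor_a} x {factor_b}"
    effects = {
        factor_a: _effect_from_contrast(factor_a, con_a, scale),
        factor_b: _effect_from_contrast(factor_b, con_b, scale),
        inter: _effect_from_contrast(inter, con_ab, scale),
    }
    return AnovaResult(factor_a=factor_a, factor_b=factor_b, effects=effects)


def between_subject_ci(
    table: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Per-condition mean and between-subject CI half-width.

    ``table`` is wide: participants × conditions.  Half-width is
    ``t_{1-(1-level)/2, n-1} * sd / sqrt(n)``; ``level = 0`` degenerates to
    zero half-width.
    """
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 participants for a between-subject CI")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    tq = sps.t.ppf(1.0 - (1.0 - level) / 2.0, n - 1) if level > 0 else 0.0
    half = tq * sd / np.sqrt(n)
    return pd.DataFrame({"mean": mean, "ci_half_width": half})


def jzs_bf_from_t(t: float, n: int, cauchy_scale: float = 0.5) -> float:
    """JZS BF10 for a one-sample/paired t statistic.

    Marginalises the likelihood of ``t`` over a Cauchy(0, ``cauchy_scale``)
    prior on the standardised effect size delta (noncentral-t likelihood,
    ncp = delta*sqrt(n)) and divides by the likelihood under delta = 0.
    Adaptive quadrature, relative tolerance 1e-8.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if cauchy_scale <= 0:
        raise ValueError("cauchy_scale must be positive")
    nu = n - 1
    rootn = np.sqrt(n)

    # integrate in the prior's CDF domain: u = F_Cauchy(delta) makes the
    # prior weight uniform on (0, 1), so the quadrature cannot miss a narrow
    # prior no matter the scale
    def integrand(u):
        delta = sps.cauchy.ppf(u, 0.0, cauchy_scale)
        return sps.nct.pdf(t, nu, delta * rootn)

    peak = float(sps.cauchy.cdf(t / rootn, 0.0, cauchy_scale))
    points = sorted({0.5, min(max(peak, 1e-12), 1.0 - 1e-12)})
    num, _ = integrate.quad(
        integrand, 0.0, 1.0, points=points, epsrel=1e-8, epsabs=0.0, limit=200
    )
    den = sps.t.pdf(t, nu)
    return float(num / den)


def jzs_paired_bf(differences, cauchy_scale: float = 0.5) -> float:
    """JZS Bayes factor (BF10) for per-participant paired differences.

    The default prior width 0.5 is the conventional narrow Cauchy used for
    within-subject effects.  BF01 is the reciprocal.  Raises on
    zero-variance differences (t undefined).
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance differences: t statistic undefined")
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    return jzs_bf_from_t(t, d.size, cauchy_scale=cauchy_scale)
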