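"""Expert-vs-novice group comparison with linear mixed-effects models.

Every participant contributes several sutures (and many segments), so all
group contrasts are fitted with a per-participant random intercept.

Suture level: ``outcome ~ skill + (1 | participant)``, REML, with the
novice-minus-expert contrast tested by a t test whose degrees of freedom are
computed with Satterthwaite's method (for the balanced two-group design this
lands close to n_participants - 2).

Segment level: ``outcome ~ skill * segment + (1 | participant)`` with the
residual variance free to differ in every segment-by-skill cell, because the
spread of both similarity and efficiency outcomes varies strongly across
task phases and skill groups.  Hypotheses are tested with type III Wald F
tests under sum-to-zero coding: the F statistic of each term is adjusted for
all other terms.  Denominator degrees of freedom are n_participants - 2 for
the (between-participant) skill term and the within-participant residual df
for segment and interaction.

Outcomes bounded on [0, 1] or [-1, 1] are analysed untransformed; a warning
is attached when observed values come within 0.01 of a bound, where
heteroscedasticity from the bounding could bias the normal-theory tests.
A Levene-type diagnostic (absolute deviations from group medians) is
provided for checking homogeneity of residual spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._lmm import fit_random_intercept, satterthwaite_df, wald_f

__all__ = [
    "StatsError",
    "MixedModelResult",
    "AnovaResult",
    "AnovaTerm",
    "LeveneResult",
    "suture_level_lmm",
    "segment_level_anova",
    "variance_homogeneity_check",
]

ANOVA_TERMS = ("skill", "segment", "skill:segment")


class StatsError(ValueError):
    """Raised for designs the models cannot be fitted on."""


@dataclass(frozen=True)
class MixedModelResult:
    """Skill contrast (novice minus expert) from a random-intercept model."""

    outcome: str
    fixed_effect_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    random_intercept_variance: float
    residual_variance: float
    df: float
    df_method: str
    n_obs: int
    n_participants: int
    singular: bool = False
    converged: bool = True
    warnings: tuple[str, ...] = ()

    @property
    def random_intercept_sd(self) -> float:
        return math.sqrt(self.random_intercept_variance)


@dataclass(frozen=True)
class AnovaTerm:
    term: str
    F: float
    p: float
    df_num: int
    df_den: float


@dataclass(frozen=True)
class AnovaResult:
    """Type III tests for skill, segment and their interaction."""

    outcome: str
    terms: tuple[AnovaTerm, ...]
    random_intercept_variance: float
    residual_variances: dict
    n_obs: int
    n_participants: int
    singular: bool = False
    converged: bool = True

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class LeveneResult:
    statistic: float
    p_value: float
    n_groups: int


def _check_design(table: pd.DataFrame, outcome: str) -> None:
    if outcome not in table.columns:
        raise StatsError(f"outcome column {outcome!r} not in table")
    if not np.issubdtype(np.asarray(table[outcome]).dtype, np.number):
        raise StatsError(f"outcome column {outcome!r} is not numeric")
    counts = table.groupby("group")["participant_id"].nunique()
    for grp in ("expert", "novice"):
        if counts.get(grp, 0) < 2:
            raise StatsError(
                f"need at least 2 participants in group {grp!r}, got {counts.get(grp, 0)}"
            )


def _bound_warnings(values: np.ndarray) -> tuple[str, ...]:
    lo, hi = (0.0, 1.0) if values.min() >= 0 else (-1.0, 1.0)
    warns = []
    if values.min() < lo + 0.01 or values.max() > hi - 0.01:
        warns.append(
            f"outcome values within 0.01 of the [{lo:g}, {hi:g}] bounds; "
            "the untransformed normal model may be strained"
        )
    return tuple(warns)


def suture_level_lmm(table: pd.DataFrame, outcome: str) -> MixedModelResult:
    """Fit ``outcome ~ skill + (1 | participant)`` on a per-suture table.

    The reported estimate is the novice-minus-expert contrast (negative
    values mean novices score lower), with a Satterthwaite t test and 95% CI.
    """
    _check_design(table, outcome)
    y = np.asarray(table[outcome], dtype=float)
    novice = (table["group"] == "novice").to_numpy().astype(float)
    X = np.column_stack([np.ones(len(y)), novice])
    fit = fit_random_intercept(y, X, groups=table["participant_id"].to_numpy())
    contrast = np.array([0.0, 1.0])
    est = float(contrast @ fit.beta)
    se = float(np.sqrt(contrast @ fit.cov_beta @ contrast))
    if fit.singular or not fit.converged:
        df = float(max(fit.n_groups - 2, 1))
        df_method = "between-participant (fallback)"
    else:
        df = satterthwaite_df(fit, contrast)
        df_method = "satterthwaite"
    tval = est / se if se > 0 else 0.0
    p = float(2 * sps.t.sf(abs(tval), df)) if se > 0 else 1.0
    tcrit = float(sps.t.ppf(0.975, df))
    return MixedModelResult(
        outcome=outcome,
        fixed_effect_estimate=est,
        ci_low=est - tcrit * se,
        ci_high=est + tcrit * se,
        p_value=p,
        random_intercept_variance=fit.sigma2_participant,
        residual_variance=fit.sigma2_residual["residual"],
        df=df,
        df_method=df_method,
        n_obs=fit.n_obs,
        n_participants=fit.n_groups,
        singular=fit.singular,
        converged=fit.converged,
        warnings=_bound_warnings(y),
    )


def _sum_coded_design(
    table: pd.DataFrame,
) -> tuple[np.ndarray, dict[str, slice], list[str]]:
    """Sum-to-zero design matrix for skill * segment; returns (X, term slices)."""
    segments = sorted(table["segment_type"].dropna().unique())
    if len(segments) < 2:
        raise StatsError(f"need at least 2 segment types, got {segments}")
    skill = np.where(table["group"] == "novice", 1.0, -1.0)
    seg_cols = []
    for seg in segments[:-1]:
        col = np.where(table["segment_type"] == seg, 1.0, 0.0)
        col = col - np.where(table["segment_type"] == segments[-1], 1.0, 0.0)
        seg_cols.append(col)
    seg_mat = np.column_stack(seg_cols)
    inter = seg_mat * skill[:, None]
    X = np.column_stack([np.ones(len(table)), skill, seg_mat, inter])
    k = len(segments) - 1
    slices = {
        "skill": slice(1, 2),
        "segment": slice(2, 2 + k),
        "skill:segment": slice(2 + k, 2 + 2 * k),
    }
    return X, slices, segments


def segment_level_anova(table: pd.DataFrame, outcome: str) -> AnovaResult:
    """Type III tests for skill, segment and skill-by-segment on per-segment data.

    Residual variances are estimated separately for every segment-by-skill
    cell; the participant random intercept is shared.
    """
    _check_design(table, outcome)
    table = table.dropna(subset=[outcome]).reset_index(drop=True)
    X, term_slices, segments = _sum_coded_design(table)
    y = np.asarray(table[outcome], dtype=float)
    cells = (table["group"].astype(str) + "/" + table["segment_type"].astype(str)).to_numpy()
    fit = fit_random_intercept(
        y, X, groups=table["participant_id"].to_numpy(), cells=cells
    )
    n_par = fit.n_groups
    p_cols = X.shape[1]
    within_df = max(fit.n_obs - p_cols - (n_par - 1), 1)
    terms = []
    for name in ANOVA_TERMS:
        sl = term_slices[name]
        q = sl.stop - sl.start
        L = np.zeros((q, p_cols))
        for r, c in enumerate(range(sl.start, sl.stop)):
            L[r, c] = 1.0
        ddf = float(max(n_par - 2, 1)) if name == "skill" else float(within_df)
        F, p = wald_f(fit, L, ddf)
        terms.append(AnovaTerm(term=name, F=F, p=p, df_num=q, df_den=ddf))
    return AnovaResult(
        outcome=outcome,
        terms=tuple(terms),
        random_intercept_variance=fit.sigma2_participant,
        residual_variances=dict(fit.sigma2_residual),
        n_obs=fit.n_obs,
        n_participants=n_par,
        singular=fit.singular,
        converged=fit.converged,
    )


def variance_homogeneity_check(groups: Sequence[np.ndarray]) -> LeveneResult:
    """Levene-type test (absolute deviations from group medians) on residual groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("need at least 2 groups of residuals")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise StatsError(f"group {i} has fewer than 2 residuals")
    stat, p = sps.levene(*arrays, center="median")
    return LeveneResult(statistic=float(stat), p_value=float(p), n_groups=len(arrays))
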