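"""Congruence between association strength and interaction strength.

Each plant-butterfly pair is placed in a plane with the co-occurrence
association strength (RII by default) on the x-axis and the literature-coded
interaction strength on the y-axis.  Splitting the plane into four
quadrants exposes the two interesting mismatch regions: pairs that
interact strongly but barely co-occur (upper left) and pairs that
aggregate spatially without a recorded interaction (lower right).

A one-way ANOVA (with Tukey HSD post hoc contrasts) tests whether mean
association strength differs between interaction-strength levels, and an
optional proportional-odds ordinal regression models the strength category
as a function of the association among positively associated pairs.  The
ordinal fit is labelled exploratory: with categorical ordinal outcomes the
parallel-lines assumption often fails and must be checked.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QUADRANTS",
    "assign_quadrants",
    "anova_by_strength",
    "tukey_hsd",
    "olr_fit",
]

logger = logging.getLogger(__name__)

QUADRANTS = ("lower-left", "lower-right", "upper-left", "upper-right")


def assign_quadrants(pairs: pd.DataFrame, x_split: float = 0.0,
                     y_split: float | None = None,
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label each pair with its quadrant and tally per-quadrant counts.

    ``pairs`` needs columns ``association_strength`` and
    ``interaction_strength``.  ``x_split`` defaults to 0 (aggregation vs.
    segregation); ``y_split`` defaults to the smallest positive interaction
    strength present (link vs. no link).  A pair is "upper"/"right" when
    its value is >= the split.
    """
    out = pairs.copy()
    x = out["association_strength"].to_numpy(dtype=float)
    y = out["interaction_strength"].to_numpy(dtype=float)
    if y_split is None:
        positive = y[y > 0]
        y_split = float(positive.min()) if positive.size else np.nextafter(0, 1)
    right = x >= x_split
    upper = y >= y_split
    labels = np.where(upper,
                      np.where(right, "upper-right", "upper-left"),
                      np.where(right, "lower-right", "lower-left"))
    out["quadrant"] = labels
    counts = {q: int((labels == q).sum()) for q in QUADRANTS}
    return out, counts


def _strength_groups(pairs: pd.DataFrame, min_size: int = 2) -> dict[float, np.ndarray]:
    groups: dict[float, np.ndarray] = {}
    for level, sub in pairs.groupby("interaction_strength"):
        vals = sub["association_strength"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < min_size:
            logger.warning("interaction-strength level %s has %d observation(s); dropped",
                           level, vals.size)
            continue
        groups[float(level)] = vals
    return groups


def anova_by_strength(pairs: pd.DataFrame) -> tuple[float, int, int, float]:
    """One-way ANOVA of association strength across interaction-strength levels.

    Levels with fewer than 2 observations are dropped with a warning.
    Returns (F, df_between, df_within, p).
    """
    groups = _strength_groups(pairs)
    if len(groups) < 2:
        raise ValueError("need at least two interaction-strength levels with >= 2 pairs")
    arrays = list(groups.values())
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return float(f), k - 1, n - k, float(p)


def tukey_hsd(pairs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise contrasts between interaction-strength levels.

    Uses the Tukey-Kramer studentized-range procedure (harmonic-mean group
    sizes) for unbalanced groups, at 1 - ``alpha`` family-wise coverage.
    Returns a DataFrame with group pair, mean difference, CI bounds and the
    family-wise adjusted p.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = _strength_groups(pairs)
    if len(groups) < 2:
        raise ValueError("need at least two interaction-strength levels with >= 2 pairs")
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[lvl] * arr.size for lvl, arr in groups.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return frame.rename(columns={"group1": "level_a", "group2": "level_b",
                                 "meandiff": "mean_diff", "p-adj": "p_adjusted",
                                 "lower": "ci_lower", "upper": "ci_upper"})


@dataclass
class OrdinalFit:
    """Result of the exploratory proportional-odds fit."""

    coefficient: float
    coefficient_se: float
    thresholds: np.ndarray
    log_likelihood: float
    n: int
    #: max absolute spread of the per-threshold binary-logit slopes; large
    #: values signal a parallel-lines (proportional-odds) violation.
    parallel_slope_range: float
    proportional_odds_ok: bool

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.coefficient - 1.959964 * self.coefficient_se,
                self.coefficient + 1.959964 * self.coefficient_se)


def olr_fit(pairs: pd.DataFrame, slope_range_tol: float = 2.0) -> OrdinalFit:
    """Proportional-odds logistic regression of interaction-strength category
    on association strength, for positively associated pairs.

    Exploratory by design: the parallel-lines diagnostic refits a binary
    logit at every category threshold and reports the spread of the slopes;
    when that spread exceeds ``slope_range_tol`` the proportional-odds
    assumption is flagged as violated and the fit should be read as a
    preliminary trend only.

    Raises ``ValueError`` with fewer than 3 outcome levels or under
    (quasi-)separation.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    sub = pairs[pairs["association_strength"] > 0].dropna(
        subset=["association_strength", "interaction_strength"])
    levels = np.sort(sub["interaction_strength"].unique())
    if levels.size < 3:
        raise ValueError("ordinal fit needs >= 3 interaction-strength levels "
                         f"among positively associated pairs (got {levels.size})")
    y = pd.Categorical(sub["interaction_strength"], categories=levels, ordered=True)
    x = sub[["association_strength"]].to_numpy(dtype=float)

    # crude separation screen: every level's predictor range must overlap
    # some other level's, else the MLE diverges
    ranges = {lvl: (g["association_strength"].min(), g["association_strength"].max())
              for lvl, g in sub.groupby("interaction_strength")}
    ordered = [ranges[lvl] for lvl in levels]
    if all(ordered[i][1] < ordered[i + 1][0] or ordered[i + 1][1] < ordered[i][0]
           for i in range(len(ordered) - 1)):
        raise ValueError("complete separation between outcome levels; "
                         "ordinal fit refused")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(y.codes, x, distr="logit")
        res = model.fit(method="bfgs", disp=False, maxiter=200)
    coef = float(res.params[0])
    se = float(res.bse[0])
    if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) > 50:
        raise ValueError("ordinal fit diverged (likely separation)")

    # parallel-lines diagnostic: binary logits at each cumulative threshold
    slopes = []
    codes = np.asarray(y.codes)
    for cut in range(1, levels.size):
        z = (codes >= cut).astype(int)
        if z.min() == z.max():
            continue
        try:
            import statsmodels.api as sm
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(z, sm.add_constant(x)).fit(disp=False, maxiter=200)
            if np.isfinite(fit.params[1]) and abs(fit.params[1]) < 50:
                slopes.append(float(fit.params[1]))
        except Exception:  # noqa: BLE001 - non-converged threshold skipped
            continue
    spread = float(np.ptp(slopes)) if len(slopes) >= 2 else float("nan")
    ok = bool(np.isfinite(spread) and spread <= slope_range_tol)
    if not ok:
        logger.warning("proportional-odds diagnostic: per-threshold slopes span %.2f; "
                       "interpret the ordinal fit with caution", spread)
    return OrdinalFit(coefficient=coef, coefficient_se=se,
                      thresholds=np.asarray(res.params[1:], dtype=float),
                      log_likelihood=float(res.llf), n=int(len(sub)),
                      parallel_slope_range=spread, proportional_odds_ok=ok)
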