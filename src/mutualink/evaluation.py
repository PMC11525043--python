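"""Accuracy framework: confusion tables, sensitivity/specificity, method
comparisons, and bipartite network summary metrics.

Known links are the strictly positive entries of the literature-coded
interaction matrix; a pair counts as *detected* when its association is
positive and significant at the chosen one-tailed level.  Negative
(segregation) associations never count as detections, since mutualism can
only show up as aggregation.

Convention (matching the standard epidemiological usage): FP = known
non-link scored significant, FN = known link missed.  Sensitivity =
TP/(TP+FN) is the probability of detecting a true link; specificity =
TN/(TN+FP) is the true-negative rate.

The module also ships, as plain CSV text, the published confusion counts
and network metrics of a two-region German grassland benchmark of these
methods (regions coded ALB and SCH), which serve as a fixed reference
surface for the ratio and chi-squared computations.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import InteractionMatrix

__all__ = [
    "ConfusionTable",
    "NetworkMetrics",
    "classify_pairs",
    "sensitivity",
    "specificity",
    "sweep_alphas",
    "compare_methods_chisq",
    "network_metrics",
    "validate_with_visits",
    "load_reference_confusion",
    "load_reference_networks",
    "DEFAULT_ALPHAS",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS = (0.05, 0.1, 0.2, 0.5)


@dataclass(frozen=True)
class ConfusionTable:
    """TP/TN/FP/FN counts for one method, community and significance level."""

    method: str
    region: str
    alpha: float
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_links(self) -> int:
        return self.TP + self.FN

    @property
    def n_nonlinks(self) -> int:
        return self.TN + self.FP

    @property
    def n_pairs(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class NetworkMetrics:
    """Bipartite network size and connectance."""

    potential: int
    realized: int

    @property
    def connectance(self) -> float:
        return self.realized / self.potential


def classify_pairs(associations: pd.DataFrame, truth: InteractionMatrix,
                   alpha: float, method: str | None = None,
                   region: str = "synthetic") -> ConfusionTable:
    """Cross-classify every pair by known link status and detection at ``alpha``.

    Detection is re-evaluated at ``alpha`` from the stored statistics and
    p-values (positive statistic and method-specific p below alpha), so one
    association table supports a sweep over significance levels.
    """
    method = method or str(associations["method"].iloc[0])
    truth_long = truth.to_long().rename(columns={"strength": "true_strength"})
    merged = associations.merge(truth_long, on=["plant", "butterfly"], how="outer",
                                indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("association table and truth matrix cover different pair sets")

    p_col = "p_adjusted" if method.startswith("spearman") else "p_upper"
    p = merged[p_col].to_numpy(dtype=float)
    stat = merged["statistic"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        detected = (stat > 0) & (p < alpha)
    detected = np.where(np.isnan(p) | np.isnan(stat), False, detected)
    link = merged["true_strength"].to_numpy(dtype=float) > 0

    return ConfusionTable(
        method=method, region=region, alpha=float(alpha),
        TP=int((link & detected).sum()),
        FN=int((link & ~detected).sum()),
        FP=int((~link & detected).sum()),
        TN=int((~link & ~detected).sum()),
    )


def sensitivity(ct: ConfusionTable) -> float:
    """Probability of detecting a true link, TP/(TP+FN); NaN if no links."""
    denom = ct.TP + ct.FN
    if denom == 0:
        logger.warning("sensitivity undefined: no known links")
        return float("nan")
    return ct.TP / denom


def specificity(ct: ConfusionTable) -> float:
    """True-negative rate, TN/(TN+FP); NaN if no known non-links."""
    denom = ct.TN + ct.FP
    if denom == 0:
        logger.warning("specificity undefined: no known non-links")
        return float("nan")
    return ct.TN / denom


def sweep_alphas(associations: pd.DataFrame, truth: InteractionMatrix,
                 alphas: Sequence[float] = DEFAULT_ALPHAS,
                 method: str | None = None, region: str = "synthetic",
                 ) -> list[ConfusionTable]:
    """One confusion table per significance cutoff (detection sets are nested,
    so TP is non-decreasing and TN non-increasing in alpha)."""
    return [classify_pairs(associations, truth, a, method=method, region=region)
            for a in alphas]


def compare_methods_chisq(ct_a: ConfusionTable, ct_b: ConfusionTable,
                          facet: str = "detection-of-links",
                          ) -> tuple[float, int, float]:
    """Yates-corrected Pearson chi-squared comparing two methods' detections.

    Rows are the two methods; columns are (TP, FN) for
    ``"detection-of-links"`` or (TN, FP) for ``"detection-of-nonlinks"``.
    Returns (X2, df, p) with df = 1.  Undefined (NaN) when a marginal
    total is zero.
    """
    if facet == "detection-of-links":
        table = np.array([[ct_a.TP, ct_a.FN], [ct_b.TP, ct_b.FN]])
    elif facet == "detection-of-nonlinks":
        table = np.array([[ct_a.TN, ct_a.FP], [ct_b.TN, ct_b.FP]])
    else:
        raise ValueError(f"unknown facet {facet!r}")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("chi-squared undefined: zero marginal total")
        return float("nan"), 1, float("nan")
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def network_metrics(realized: int | ConfusionTable, n_plants: int,
                    n_butterflies: int) -> NetworkMetrics:
    """Potential pair count, realized links and connectance.

    ``realized`` is either a TP count from a confusion table (a method's
    reconstructed network) or the known-link count (the empirical network).
    """
    if n_plants < 1 or n_butterflies < 1:
        raise ValueError("need at least one species in each guild")
    if isinstance(realized, ConfusionTable):
        realized = realized.TP
    return NetworkMetrics(potential=n_plants * n_butterflies, realized=int(realized))


def validate_with_visits(visits: pd.DataFrame, associations: pd.DataFrame,
                         truth: InteractionMatrix, alpha: float = 0.2) -> dict:
    """Validate association scores against independent flower-visitation counts.

    ``visits`` is a long table (plant, butterfly, visits >= 0).  Restricted
    to the visited pairs shared with the association table, the report
    gives: (1) count and percentage of pairs with a negative association
    statistic; (2) OLS fit (slope, intercept, R^2) of visits on the
    association values of significant positive pairs at ``alpha``;
    (3) Spearman rho/p between visits and literature interaction strengths.
    """
    if (visits["visits"] < 0).any():
        raise ValueError("visit counts must be non-negative")
    merged = associations.merge(visits, on=["plant", "butterfly"], how="inner")
    if merged.empty:
        logger.warning("no overlapping pairs between visits and associations")
        return {"n_pairs": 0}
    truth_long = truth.to_long()
    merged = merged.merge(truth_long, on=["plant", "butterfly"], how="left")
    merged["strength"] = merged["strength"].fillna(0.0)

    stat = merged["statistic"].to_numpy(dtype=float)
    neg = int((stat < 0).sum())
    report: dict = {
        "n_pairs": int(len(merged)),
        "negative_count": neg,
        "negative_percent": 100.0 * neg / len(merged),
    }

    method = str(merged["method"].iloc[0])
    p_col = "p_adjusted" if method.startswith("spearman") else "p_upper"
    p = merged[p_col].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        pos_sig = (stat > 0) & (p < alpha)
    pos_sig = np.where(np.isnan(p) | np.isnan(stat), False, pos_sig)
    sub = merged[pos_sig]
    if len(sub) >= 3 and sub["statistic"].nunique() > 1:
        fit = stats.linregress(sub["statistic"], sub["visits"])
        report["ols"] = {"slope": float(fit.slope), "intercept": float(fit.intercept),
                         "r_squared": float(fit.rvalue ** 2), "p": float(fit.pvalue),
                         "n": int(len(sub))}
    else:
        report["ols"] = None

    if merged["strength"].nunique() > 1 and merged["visits"].nunique() > 1:
        rho, p_rho = stats.spearmanr(merged["visits"], merged["strength"])
        report["strength_spearman"] = {"rho": float(rho), "p": float(p_rho)}
    else:
        report["strength_spearman"] = None
    return report


# ---------------------------------------------------------------------------
# Published reference tables (two-region grassland benchmark)
# ---------------------------------------------------------------------------

# Confusion counts per method, region and significance level, as printed in
# the benchmark's accuracy table.  Methods: RII = RII with pairwise null
# models; Probabilistic = analytic hypergeometric; Plant/Flower cor =
# Spearman rank correlation on plant / flower-availability abundances with
# BH correction.
_REFERENCE_CONFUSION_CSV = """\
method,region,alpha,TP,TN,FP,FN
RII,ALB,0.05,47,1852,4216,770
RII,ALB,0.1,123,1359,4709,694
RII,ALB,0.2,206,875,5193,611
RII,ALB,0.5,414,0,6068,403
RII,SCH,0.05,11,244,613,203
RII,SCH,0.1,31,196,661,183
RII,SCH,0.2,62,117,740,152
RII,SCH,0.5,123,0,857,91
Probabilistic,ALB,0.05,70,2545,3523,747
Probabilistic,ALB,0.1,105,2330,3738,712
Probabilistic,ALB,0.2,171,1882,4186,646
Probabilistic,ALB,0.5,319,1101,4967,498
Probabilistic,SCH,0.05,11,347,510,203
Probabilistic,SCH,0.1,22,318,539,192
Probabilistic,SCH,0.2,29,283,574,185
Probabilistic,SCH,0.5,85,193,664,129
Plant cor,ALB,0.05,67,1808,4260,750
Plant cor,ALB,0.1,98,1659,4409,719
Plant cor,ALB,0.2,131,1455,4613,686
Plant cor,ALB,0.5,196,1017,5051,621
Plant cor,SCH,0.05,5,261,596,209
Plant cor,SCH,0.1,9,247,610,205
Plant cor,SCH,0.2,11,240,617,203
Plant cor,SCH,0.5,38,192,665,176
Flower cor,ALB,0.05,45,1237,2271,629
Flower cor,ALB,0.1,66,1155,2353,608
Flower cor,ALB,0.2,84,1051,2457,590
Flower cor,ALB,0.5,160,774,2734,514
Flower cor,SCH,0.05,0,182,392,167
Flower cor,SCH,0.1,3,181,393,164
Flower cor,SCH,0.2,5,180,394,162
Flower cor,SCH,0.5,31,136,438,136
"""

# Network-level counts at alpha = 0.2: species counts per guild and realized
# links (TP for the methods; known links for the empirical rows).
_REFERENCE_NETWORKS_CSV = """\
method,region,potential,realized
Empirical,ALB,6885,817
RII null models,ALB,6885,206
Probabilistic,ALB,6885,171
Plant correlation,ALB,6885,131
Flower correlation,ALB,4182,84
Empirical,SCH,1071,214
RII null models,SCH,1071,62
Probabilistic,SCH,1071,29
Plant correlation,SCH,1071,11
Flower correlation,SCH,741,5
"""


def load_reference_confusion() -> pd.DataFrame:
    """Published confusion counts (method, region, alpha, TP, TN, FP, FN)."""
    return pd.read_csv(io.StringIO(_REFERENCE_CONFUSION_CSV))


def load_reference_networks() -> pd.DataFrame:
    """Published network counts at alpha = 0.2 (potential and realized links)."""
    return pd.read_csv(io.StringIO(_REFERENCE_NETWORKS_CSV))


def reference_confusion_tables() -> list[ConfusionTable]:
    """The reference counts as :class:`ConfusionTable` objects."""
    return [ConfusionTable(method=r.method, region=r.region, alpha=float(r.alpha),
                           TP=int(r.TP), TN=int(r.TN), FP=int(r.FP), FN=int(r.FN))
            for r in load_reference_confusion().itertuples()]
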