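"""Pairwise species-association methods.

Three methods are implemented, the first two on presence/absence data and
the third on abundances:

* **RII** — the relative interaction intensity index transplanted to
  co-occurrence counts, ``(O - E) / (O + E)`` with ``E = n1*n2/S`` the
  expected number of co-occupied sites under independent placement.  RII
  lies in [-1, 1], is symmetric around zero (positive = aggregation,
  negative = segregation) and saturates sigmoidally.  Significance comes
  from the fixed-margin null model in :mod:`mutualink.null_models`.
* **Probabilistic** — the analytic hypergeometric probability of observing
  more than ``O`` co-occupied sites when both occupancy patterns are placed
  uniformly at random, with the effect size ``(O - E)/S`` standardized by
  the number of sites.
* **Spearman rank correlation** of the two abundance vectors across sites,
  with Benjamini-Hochberg control of the false discovery rate over all
  pairs of a run.

The exact expression of RII on counts is a design choice documented in
``docs/methods.md``: the published index is defined on performance
measures, and its standard form is applied here to observed/expected
co-occurrence counts, consistent with the stated range and symmetry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import permutations
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import OccurrenceData

__all__ = [
    "PairCounts",
    "expected_cooccurrence",
    "rii",
    "hypergeom_pmf",
    "prob_tails",
    "effect_size_standardized",
    "null_detection_rate",
    "spearman_association",
    "bh_adjust",
    "run_method",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("rii_null", "probabilistic", "spearman_plants", "spearman_flowers")


@dataclass(frozen=True)
class PairCounts:
    """Sufficient statistics of one species pair's joint occupancy.

    S sites in total; the two species occupy n1 and n2 sites and co-occur
    at O of them.  Feasibility: max(0, n1+n2-S) <= O <= min(n1, n2).
    """

    S: int
    n1: int
    n2: int
    O: int

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be a positive number of sites")
        for n in (self.n1, self.n2):
            if not 0 <= n <= self.S:
                raise ValueError(f"occupancy {n} outside [0, {self.S}]")
        lo, hi = max(0, self.n1 + self.n2 - self.S), min(self.n1, self.n2)
        if not lo <= self.O <= hi:
            raise ValueError(f"co-occurrence {self.O} outside feasible range [{lo}, {hi}]")


def expected_cooccurrence(pc: PairCounts) -> float:
    """Expected co-occupied sites under independence: E = n1*n2/S."""
    return pc.n1 * pc.n2 / pc.S


def rii(pc: PairCounts) -> float:
    """Relative interaction intensity on counts: (O - E)/(O + E), in [-1, 1].

    When O + E = 0 (possible only if one species is absent everywhere, which
    forces O = 0) the association is defined as 0.
    """
    e = expected_cooccurrence(pc)
    denom = pc.O + e
    if denom == 0:
        return 0.0
    return (pc.O - e) / denom


def effect_size_standardized(pc: PairCounts) -> float:
    """Co-occurrence effect size standardized by the number of sites: (O - E)/S."""
    return (pc.O - expected_cooccurrence(pc)) / pc.S


def hypergeom_pmf(j: int, pc: PairCounts, exact: bool = False) -> float | Fraction:
    """Probability of exactly ``j`` co-occupied sites under random placement.

    Both occupancy patterns are placed uniformly at random over the S
    sites with their occupancies fixed; the number of co-occupied sites is
    then hypergeometric:

        P(j) = C(S, j) C(S-j, n1-j) C(S-n1, n2-j) / [C(S, n1) C(S, n2)]

    With ``exact=True`` the value is returned as an exact
    :class:`~fractions.Fraction`.
    """
    S, n1, n2 = pc.S, pc.n1, pc.n2
    if j < max(0, n1 + n2 - S) or j > min(n1, n2):
        return Fraction(0) if exact else 0.0
    num = math.comb(S, j) * math.comb(S - j, n1 - j) * math.comb(S - n1, n2 - j)
    den = math.comb(S, n1) * math.comb(S, n2)
    frac = Fraction(num, den)
    return frac if exact else float(frac)


def prob_tails(pc: PairCounts, exact: bool = False
               ) -> tuple[float, float, float] | tuple[Fraction, Fraction, Fraction]:
    """Tail probabilities of the analytic co-occurrence distribution.

    Returns ``(p_gt, p_lt, p_eq)``: the probabilities of strictly more,
    strictly fewer, and exactly the observed number of co-occupied sites.
    They sum to 1.  A positive association is scored significant when
    ``p_gt < alpha`` (aggregation tail).
    """
    lo, hi = max(0, pc.n1 + pc.n2 - pc.S), min(pc.n1, pc.n2)
    pmf = {j: hypergeom_pmf(j, pc, exact=True) for j in range(lo, hi + 1)}
    p_gt = sum((p for j, p in pmf.items() if j > pc.O), Fraction(0))
    p_lt = sum((p for j, p in pmf.items() if j < pc.O), Fraction(0))
    p_eq = pmf[pc.O]
    if exact:
        return p_gt, p_lt, p_eq
    return float(p_gt), float(p_lt), float(p_eq)


def null_detection_rate(pc: PairCounts, alpha: float, tail: str = "strict") -> float:
    """Exact probability that an independent pair is flagged significant positive.

    Under random placement of the two occupancy patterns the co-occurrence
    count is hypergeometric, so the operating level of the one-tailed
    discrete tests can be computed in closed form: the pair is detected
    when its count exceeds expectation and its upper-tail probability falls
    below ``alpha``.  ``tail="strict"`` uses P(X > O) (the analytic
    probabilistic method, liberal on discrete support); ``tail="inclusive"``
    uses P(X >= O) (the large-ensemble limit of the null-model RII test,
    where ties count toward the tail, conservative).  ``pc.O`` is ignored.

    This is the reference value for false-positive calibration checks on
    decoupled synthetic communities: because of the discreteness of the
    support, the attainable level differs from ``alpha`` itself.
    """
    if tail not in ("strict", "inclusive"):
        raise ValueError(f"unknown tail {tail!r}")
    lo, hi = max(0, pc.n1 + pc.n2 - pc.S), min(pc.n1, pc.n2)
    js = np.arange(lo, hi + 1)
    pmf = np.array([float(hypergeom_pmf(int(j), pc)) for j in js])
    upper_incl = np.cumsum(pmf[::-1])[::-1]          # P(X >= j)
    upper = upper_incl if tail == "inclusive" else upper_incl - pmf
    e = expected_cooccurrence(pc)
    return float((pmf * ((upper < alpha) & (js > e))).sum())


def spearman_association(x: np.ndarray, y: np.ndarray,
                         method: Literal["t", "exact"] = "t",
                         ) -> tuple[float, float]:
    """Spearman rank correlation of two abundance vectors across sites.

    Mid-ranks (average ranks) are used for ties; the two-sided p-value
    comes from the large-sample t approximation, or from full enumeration
    of site permutations when ``method="exact"`` (only for <= 10 sites).

    A constant vector leaves the correlation undefined: (nan, nan) is
    returned with a logged warning, and callers treat the pair as
    non-significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 sites for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant abundance vector: Spearman correlation undefined; "
                       "pair will be treated as non-significant")
        return float("nan"), float("nan")
    if method == "t":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "exact":
        n = x.size
        if n > 10:
            raise ValueError("exact permutation p-value limited to <= 10 sites")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
            total += 1
        return float(obs), count / total
    raise ValueError(f"unknown method {method!r}")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    NaNs (undefined tests, e.g. constant species) pass through as NaN and
    do not count toward the family size m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D list of p-values")
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# All-pairs runs
# ---------------------------------------------------------------------------

def _pair_counts_matrix(plants_bin: np.ndarray, butterflies_bin: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Occupancies and co-occurrence counts for every plant x butterfly pair."""
    S = plants_bin.shape[0]
    n_p = plants_bin.sum(axis=0).astype(int)            # per plant
    n_b = butterflies_bin.sum(axis=0).astype(int)       # per butterfly
    O = (plants_bin.T.astype(np.int64) @ butterflies_bin.astype(np.int64))
    return n_p, n_b, O, S


def _spearman_all_pairs(pa: np.ndarray, ba: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized mid-rank Spearman rho and t-approximation p for all pairs.

    ``pa`` is sites x plants abundance, ``ba`` sites x butterflies.
    Constant columns yield NaN.
    """
    S = pa.shape[0]
    rp = stats.rankdata(pa, axis=0)
    rb = stats.rankdata(ba, axis=0)
    rp = rp - rp.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    sp = np.sqrt((rp ** 2).sum(axis=0))
    sb = np.sqrt((rb ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rp.T @ rb) / np.outer(sp, sb)
    rho[:, sb == 0] = np.nan
    rho[sp == 0, :] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((S - 2) / (1.0 - rho ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=S - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return rho, p


def run_method(plants: OccurrenceData, butterflies: OccurrenceData,
               method: str, alpha: float = 0.2,
               null_config=None) -> pd.DataFrame:
    """Score every plant x butterfly pair with one association method.

    Returns a DataFrame with one row per pair and columns ``plant``,
    ``butterfly``, ``method``, ``statistic``, ``p_upper``, ``p_lower``,
    ``p_adjusted``, ``observed`` and ``significant``.  Significance of a
    positive association is ``statistic > 0`` and the method-specific
    p-value below ``alpha``: the null-model upper tail for ``rii_null``,
    the aggregation tail ``p_gt`` for ``probabilistic``, and the
    BH-adjusted two-sided p for the Spearman variants.

    ``spearman_flowers`` behaves identically to ``spearman_plants``; pass
    flower-availability data (log-transformed) as ``plants``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if plants.sites != butterflies.sites:
        raise ValueError("plants and butterflies must share an identical site list")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")

    pb = plants.presence
    bb = butterflies.presence
    n_p, n_b, O, S = _pair_counts_matrix(pb, bb)
    n_pl, n_bu = len(plants.species), len(butterflies.species)
    E = np.outer(n_p, n_b) / S

    p_upper = np.full((n_pl, n_bu), np.nan)
    p_lower = np.full((n_pl, n_bu), np.nan)
    p_adj = np.full((n_pl, n_bu), np.nan)

    if method == "rii_null":
        from .null_models import NullModelConfig, pairwise_null_pvalues
        config = null_config if null_config is not None else NullModelConfig()
        with np.errstate(invalid="ignore"):
            statistic = np.where(O + E > 0, (O - E) / np.where(O + E > 0, O + E, 1.0), 0.0)
        p_upper, p_lower = pairwise_null_pvalues(pb, bb, config)
        p_sig = p_upper
    elif method == "probabilistic":
        statistic = (O - E) / S
        for i in range(n_pl):
            for j in range(n_bu):
                pc = PairCounts(S=S, n1=int(n_p[i]), n2=int(n_b[j]), O=int(O[i, j]))
                p_gt, p_lt, _ = prob_tails(pc)
                p_upper[i, j], p_lower[i, j] = p_gt, p_lt
        p_sig = p_upper
    else:  # spearman variants
        statistic, p_two = _spearman_all_pairs(plants.abundance, butterflies.abundance)
        p_upper = p_two
        p_adj = bh_adjust(p_two.ravel()).reshape(p_two.shape)
        p_sig = p_adj

    with np.errstate(invalid="ignore"):
        significant = (statistic > 0) & (p_sig < alpha)
    significant = np.where(np.isnan(p_sig), False, significant)

    pl_idx, bu_idx = np.meshgrid(np.arange(n_pl), np.arange(n_bu), indexing="ij")
    return pd.DataFrame({
        "plant": np.asarray(plants.species)[pl_idx.ravel()],
        "butterfly": np.asarray(butterflies.species)[bu_idx.ravel()],
        "method": method,
        "statistic": np.asarray(statistic, dtype=float).ravel(),
        "p_upper": p_upper.ravel(),
        "p_lower": p_lower.ravel(),
        "p_adjusted": p_adj.ravel(),
        "observed": O.ravel(),
        "significant": significant.ravel().astype(bool),
    })
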