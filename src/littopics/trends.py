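"""Hot/cold topic detection from yearly topic prevalence.

For each topic the trend signal is the per-year mean of theta-hat (the
per-document topic proportions) over the documents published that year.
An ordinary least squares regression of that series on calendar year gives a
slope and a two-sided t-test p-value (n - 2 degrees of freedom); topics with
a significantly positive slope are "hot", significantly negative "cold".
Significance is tallied at the four conventional tiers 0.05, 0.01, 0.001
and 0.0001, with p equal to a level counting as significant at it.

No multiple-testing correction is applied by default: the summary counts
deliberately tally raw per-level significance across topics. A
Benjamini-Hochberg option is available for users who want FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "YearlyPrevalence",
    "TopicTrend",
    "TopicTrendAnalyzer",
    "yearly_mean_theta",
    "trend_test",
    "classify_topics",
]

DEFAULT_LEVELS = (0.05, 0.01, 0.001, 0.0001)


@dataclass
class YearlyPrevalence:
    """One topic's mean theta per publication year (years with docs only)."""

    topic_id: int
    years: np.ndarray
    mean_theta: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.mean_theta = np.asarray(self.mean_theta, dtype=float)
        if self.years.shape != self.mean_theta.shape:
            raise ValueError("years and mean_theta must have equal length")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")


@dataclass
class TopicTrend:
    """OLS trend of a topic's yearly prevalence and its hot/cold call.

    ``p_value`` is NaN when undefined (fewer than 3 year points, or a
    zero-variance series). ``tier`` is the finest significance level
    attained, or None.
    """

    topic_id: int
    slope: float
    p_value: float
    direction: str  # "hot" | "cold" | "none"
    tier: float | None


def yearly_mean_theta(
    theta: np.ndarray,
    doc_years,
    topic_id: int,
    exclude_mask=None,
) -> YearlyPrevalence:
    """Average a topic's theta column within each publication year.

    Documents flagged in ``exclude_mask`` (e.g. empty abstracts given a
    uniform theta row) are left out. Years with no contributing documents
    are omitted from the series.
    """
    theta = np.asarray(theta, dtype=float)
    doc_years = np.asarray(doc_years, dtype=int)
    if doc_years.shape[0] != theta.shape[0]:
        raise ValueError("doc_years length must match theta row count")
    keep = np.ones(theta.shape[0], dtype=bool)
    if exclude_mask is not None:
        keep &= ~np.asarray(exclude_mask, dtype=bool)
    col = theta[keep, topic_id]
    yrs = doc_years[keep]
    if yrs.size == 0:
        return YearlyPrevalence(topic_id, np.array([], dtype=int), np.array([]))
    series = pd.Series(col).groupby(yrs).mean()
    return YearlyPrevalence(topic_id, series.index.to_numpy(), series.to_numpy())


def trend_test(prevalence: YearlyPrevalence) -> TopicTrend:
    """OLS of mean theta on year with a two-sided slope t-test."""
    y = prevalence.mean_theta
    x = prevalence.years.astype(float)
    if x.size < 3:
        return TopicTrend(prevalence.topic_id, slope=np.nan if x.size < 2 else _slope2(x, y),
                          p_value=np.nan, direction="none", tier=None)
    if np.ptp(y) == 0.0:
        return TopicTrend(prevalence.topic_id, 0.0, np.nan, "none", None)
    res = stats.linregress(x, y)
    slope = float(res.slope)
    p = float(res.pvalue)
    direction, tier = _call_direction(slope, p)
    return TopicTrend(prevalence.topic_id, slope, p, direction, tier)


def _slope2(x, y) -> float:
    # slope through two points; trend still "undefined" (no test possible)
    return float((y[1] - y[0]) / (x[1] - x[0]))


def _call_direction(slope: float, p: float, levels=DEFAULT_LEVELS) -> tuple[str, float | None]:
    if not np.isfinite(p) or p > max(levels) or slope == 0.0:
        return "none", None
    tier = min(lvl for lvl in levels if p <= lvl)
    return ("hot" if slope > 0 else "cold"), tier


def classify_topics(
    trends: list[TopicTrend],
    levels=DEFAULT_LEVELS,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-level counts of significantly falling/rising topics.

    Returns a table with one row per significance level and columns
    ``negative`` (cold), ``positive`` (hot) and ``total``; a topic counts at
    a level when its p-value is <= the level (undefined p-values never
    count). With ``fdr=True`` p-values are Benjamini-Hochberg adjusted
    before tallying.
    """
    levels = sorted(levels, reverse=True)
    slopes = np.array([t.slope for t in trends], dtype=float)
    pvals = np.array([t.p_value for t in trends], dtype=float)
    defined = np.isfinite(pvals) & np.isfinite(slopes)
    if fdr and defined.any():
        adj = pvals.copy()
        adj[defined] = stats.false_discovery_control(pvals[defined])
        pvals = adj
    rows = []
    for lvl in levels:
        sig = defined & (pvals <= lvl)
        neg = int(np.sum(sig & (slopes < 0)))
        pos = int(np.sum(sig & (slopes > 0)))
        rows.append({"level": lvl, "negative": neg, "positive": pos, "total": neg + pos})
    return pd.DataFrame(rows).set_index("level")


class TopicTrendAnalyzer(BaseEstimator):
    """Compute yearly prevalence, per-topic trends and the level summary.

    Parameters
    ----------
    levels : tuple of float
        Significance tiers for the hot/cold tally.
    fdr : bool, default=False
        Apply Benjamini-Hochberg adjustment before tallying.

    Attributes
    ----------
    prevalence_ : list of YearlyPrevalence
    trends_ : list of TopicTrend
    summary_ : pd.DataFrame with negative/positive/total per level
    trend_table_ : pd.DataFrame, one row per topic sorted by slope
    """

    def __init__(self, levels=DEFAULT_LEVELS, fdr: bool = False):
        self.levels = levels
        self.fdr = fdr

    def fit(self, theta, doc_years, exclude_mask=None):
        theta = np.asarray(theta, dtype=float)
        n_topics = theta.shape[1]
        self.prevalence_ = [
            yearly_mean_theta(theta, doc_years, k, exclude_mask) for k in range(n_topics)
        ]
        self.trends_ = [trend_test(p) for p in self.prevalence_]
        self.summary_ = classify_topics(self.trends_, self.levels, fdr=self.fdr)
        self.trend_table_ = (
            pd.DataFrame(
                {
                    "topic_id": [t.topic_id for t in self.trends_],
                    "slope": [t.slope for t in self.trends_],
                    "p_value": [t.p_value for t in self.trends_],
                    "direction": [t.direction for t in self.trends_],
                    "tier": [t.tier for t in self.trends_],
                }
            )
            .sort_values("slope", ascending=False)
            .reset_index(drop=True)
        )
        return self

    def transform(self, X=None):
        check_is_fitted(self, "summary_")
        return self.summary_
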