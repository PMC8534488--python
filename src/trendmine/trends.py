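"""Topic x emotion temporal trends and stationarity testing.

Topic and emotion assignments are joined on document ids into a tidy
table, aggregated into daily proportion series (optionally smoothed
with a centered 7-day rolling mean), and each emotion series is tested
for stationarity with an augmented Dickey-Fuller regression (constant
term, AIC lag selection).  Days with zero volume in scope yield missing
proportions rather than zeros, so silent days never fabricate
sentiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

from .corpus_io import TweetCollection
from .onmf import UNASSIGNED, TopicAssignment
from .sentiment import EMOTION_LABELS, EmotionMatrix

__all__ = [
    "TimeSeries",
    "AdfResult",
    "merge_topic_emotion",
    "daily_topic_series",
    "daily_emotion_series",
    "weekly_smooth",
    "adf_stationarity",
    "trends_to_frame",
    "adf_report",
]


@dataclass
class TimeSeries:
    """Per-day series on a contiguous calendar grid; NaN marks missing."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    kind: str = "proportion"  # or "count"
    smoothing: str = "none"  # or "rolling7"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values length mismatch")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("dates must be strictly increasing")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.dates)


@dataclass(frozen=True)
class AdfResult:
    statistic: float
    p_value: float
    n_lags: int
    stationary: bool
    alpha: float = 0.05


def merge_topic_emotion(
    topics: TopicAssignment,
    emotions: EmotionMatrix,
    col: TweetCollection,
) -> pd.DataFrame:
    """Join topic, emotion and timestamp on document id.

    Returns a DataFrame indexed by ``doc_id`` with columns
    ``timestamp`` (UTC), ``topic`` (int, -1 for unassigned) and
    ``emotion``.  The three inputs must cover identical id sets.
    """
    sets = {
        "topics": set(topics.doc_ids),
        "emotions": set(emotions.doc_ids),
        "corpus": set(col.doc_ids),
    }
    union = set.union(*sets.values())
    if not union:
        raise ValueError("empty inputs")
    offenders = {
        name: sorted(union - ids)[:5] for name, ids in sets.items() if ids != union
    }
    if offenders:
        raise ValueError(f"doc id mismatch; missing per input (first 5): {offenders}")

    topic_by_id = dict(zip(topics.doc_ids, topics.topics))
    emo_by_id = dict(zip(emotions.doc_ids, emotions.x_rep))
    rows = {
        r.id: (pd.Timestamp(r.created_at), int(topic_by_id[r.id]), emo_by_id[r.id])
        for r in col
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["timestamp", "topic", "emotion"]
    )
    df.index.name = "doc_id"
    return df


def _date_grid(table: pd.DataFrame) -> pd.DatetimeIndex:
    days = table["timestamp"].dt.normalize().dt.tz_localize(None)
    return pd.date_range(days.min(), days.max(), freq="D")


def daily_topic_series(table: pd.DataFrame, topic: int) -> TimeSeries:
    """Daily share of assigned documents carrying ``topic``; days with no
    assigned documents are missing."""
    if table.empty:
        raise ValueError("empty table")
    grid = _date_grid(table)
    assigned = table[table["topic"] != UNASSIGNED]
    day = assigned["timestamp"].dt.normalize().dt.tz_localize(None)
    totals = day.value_counts().reindex(grid, fill_value=0)
    hits = day[assigned["topic"] == topic].value_counts().reindex(grid, fill_value=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = hits.to_numpy(float) / totals.to_numpy(float)
    frac[totals.to_numpy() == 0] = np.nan
    return TimeSeries(dates=grid, values=frac, kind="proportion")


def daily_emotion_series(
    table: pd.DataFrame, scope: int | None = None
) -> dict[str, TimeSeries]:
    """Daily proportion of each of the six labels, overall or within one
    topic.  Per day the six proportions sum to 1 where volume > 0."""
    if table.empty:
        raise ValueError("empty table")
    grid = _date_grid(table)
    sub = table if scope is None else table[table["topic"] == scope]
    day = sub["timestamp"].dt.normalize().dt.tz_localize(None)
    totals = day.value_counts().reindex(grid, fill_value=0).to_numpy(float)
    out: dict[str, TimeSeries] = {}
    for label in EMOTION_LABELS:
        hits = (
            day[sub["emotion"] == label]
            .value_counts()
            .reindex(grid, fill_value=0)
            .to_numpy(float)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = hits / totals
        frac[totals == 0] = np.nan
        out[label] = TimeSeries(dates=grid, values=frac, kind="proportion")
    return out


def weekly_smooth(series: TimeSeries) -> TimeSeries:
    """Centered 7-day rolling mean with shrinking windows at the edges."""
    sm = series.to_series().rolling(7, center=True, min_periods=1).mean()
    return TimeSeries(
        dates=series.dates,
        values=sm.to_numpy(),
        kind=series.kind,
        smoothing="rolling7",
    )


def adf_stationarity(series: TimeSeries, alpha: float = 0.05) -> AdfResult:
    """Augmented Dickey-Fuller unit-root test (constant term, AIC lag
    selection up to floor((n-1)^(1/3))); rejection means stationary."""
    x = series.values[~np.isnan(series.values)]
    n = x.size
    if n < 10:
        raise ValueError(f"series too short for the test: {n} < 10 points")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance: series is constant")
    maxlag = int(np.floor((n - 1) ** (1.0 / 3.0)))
    stat, pvalue, usedlag, *_ = adfuller(
        x, maxlag=maxlag, regression="c", autolag="AIC"
    )
    return AdfResult(
        statistic=float(stat),
        p_value=float(pvalue),
        n_lags=int(usedlag),
        stationary=bool(pvalue < alpha),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Tidy export
# ---------------------------------------------------------------------------


def trends_to_frame(named: dict[tuple[str, str], TimeSeries]) -> pd.DataFrame:
    """Flatten ``{(scope, key): series}`` into a tidy frame
    (date, scope, key, value, smoothing)."""
    rows = []
    for (scope, key), ts in named.items():
        for d, v in zip(ts.dates, ts.values):
            rows.append(
                {
                    "date": d.date().isoformat(),
                    "scope": scope,
                    "key": key,
                    "value": v,
                    "smoothing": ts.smoothing,
                }
            )
    return pd.DataFrame(rows, columns=["date", "scope", "key", "value", "smoothing"])


def adf_report(results: dict[str, AdfResult]) -> pd.DataFrame:
    rows = [
        {
            "series": name,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "n_lags": r.n_lags,
            "stationary": r.stationary,
        }
        for name, r in results.items()
    ]
    return pd.DataFrame(
        rows, columns=["series", "statistic", "p_value", "n_lags", "stationary"]
    )
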