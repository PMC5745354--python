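"""Monthly aggregation and trend statistics.

Everything downstream of classification flows through one tidy panel:
counts per (calendar month x class x topic x polarity), with polarity only
meaningful for layperson tweets. From the panel this module derives topic
volume rankings, per-class topic proportions, Pearson correlations between
the promotional and layperson monthly series of each topic, and monthly
sentiment-score trajectories.

Volume counts attribute each tweet to its primary topic only; tweets with
no topic above the cutoff are tallied under topic "none" and excluded from
proportions. Months are calendar months in UTC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import LAYPERSON, PROMOTIONAL

NO_TOPIC = "none"


def month_key(ts: datetime) -> str:
    """Calendar month of a timestamp in UTC, as "YYYY-MM"."""
    if ts.tzinfo is not None:
        ts = ts.astimezone(timezone.utc)
    return f"{ts.year:04d}-{ts.month:02d}"


def build_panel(
    tweets: Sequence[dict],
    months: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Aggregate classified tweets into a tidy monthly panel.

    Each element of *tweets* is a mapping with keys ``timestamp``
    (datetime), ``label`` (class), optional ``topic`` (str or None) and
    optional ``sentiment``. When *months* is given, tweets outside the
    range are excluded with a warning; otherwise months are inferred.

    Returns a DataFrame with columns month, class, topic, polarity, count.
    """
    records = []
    dropped = 0
    for tw in tweets:
        m = month_key(tw["timestamp"])
        if months is not None and m not in months:
            dropped += 1
            continue
        topic = tw.get("topic") or NO_TOPIC
        polarity = tw.get("sentiment") or ""
        if tw["label"] != LAYPERSON:
            polarity = ""
        records.append((m, tw["label"], topic, polarity))
    if dropped:
        warnings.warn(
            f"{dropped} tweet(s) outside the configured month range were excluded"
        )
    if not records:
        return pd.DataFrame(
            columns=["month", "class", "topic", "polarity", "count"]
        )
    df = pd.DataFrame(records, columns=["month", "class", "topic", "polarity"])
    panel = (
        df.groupby(["month", "class", "topic", "polarity"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return panel


def topic_volume_ranking(panel: pd.DataFrame) -> list[tuple[str, int]]:
    """Topics ordered by descending total tweet volume, ties lexicographic."""
    if panel.empty:
        raise ValueError("panel is empty")
    totals = panel.groupby("topic")["count"].sum()
    return sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))


def topic_proportions(panel: pd.DataFrame, class_label: str) -> dict[str, float]:
    """Proportion of each topic within one class, excluding topic "none"."""
    sub = panel[(panel["class"] == class_label) & (panel["topic"] != NO_TOPIC)]
    total = sub["count"].sum()
    if total == 0:
        raise ValueError(f"no topic-assigned tweets in class {class_label!r}")
    props = sub.groupby("topic")["count"].sum() / total
    return {str(k): float(v) for k, v in props.items()}


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float | None, float | None]:
    """Sample Pearson r with a two-sided p-value from the t distribution.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom. A constant
    series has no defined correlation: returns (None, None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0 or sy == 0:
        return None, None
    r = float((dx * dy).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return r, p


@dataclass
class CorrelationResult:
    """Pearson correlation of one topic's promotional vs layperson volumes."""

    topic: str
    r: float | None
    p: float | None
    n: int


def _monthly_series(
    panel: pd.DataFrame, class_label: str, topic: str, months: Sequence[str]
) -> np.ndarray:
    sub = panel[(panel["class"] == class_label) & (panel["topic"] == topic)]
    by_month = sub.groupby("month")["count"].sum()
    return np.array([by_month.get(m, 0) for m in months], dtype=float)


def correlation_table(panel: pd.DataFrame) -> list[CorrelationResult]:
    """Per-topic Pearson correlation of monthly promotional vs layperson volumes."""
    months = sorted(panel["month"].unique())
    if len(months) < 3:
        raise ValueError("need at least 3 months for correlation")
    topics = sorted(
        t for t in panel["topic"].unique() if t != NO_TOPIC
    )
    out = []
    for topic in topics:
        promo = _monthly_series(panel, PROMOTIONAL, topic, months)
        lay = _monthly_series(panel, LAYPERSON, topic, months)
        r, p = pearson_correlation(promo, lay)
        out.append(CorrelationResult(topic=topic, r=r, p=p, n=len(months)))
    return out


def format_p(p: float | None) -> str:
    """Render a p-value to 3 decimals, with values below 0.001 as "<.001"."""
    if p is None:
        return "NA"
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}"


def sentiment_trajectory(
    panel: pd.DataFrame, topic: str, months: Sequence[str] | None = None
) -> pd.Series:
    """Monthly normalized sentiment score for one topic's layperson tweets.

    Score per month is (pos - neg) / total over that topic's layperson
    tweets; months with no such tweets are NaN (missing, not zero).
    """
    if months is None:
        months = sorted(panel["month"].unique())
    sub = panel[
        (panel["class"] == LAYPERSON)
        & (panel["topic"] == topic)
        & (panel["polarity"] != "")
    ]
    values = []
    for m in months:
        mm = sub[sub["month"] == m]
        pos = int(mm.loc[mm["polarity"] == "positive", "count"].sum())
        neg = int(mm.loc[mm["polarity"] == "negative", "count"].sum())
        total = int(mm["count"].sum())
        values.append((pos - neg) / total if total > 0 else np.nan)
    return pd.Series(values, index=list(months), name=topic)
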